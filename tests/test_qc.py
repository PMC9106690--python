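"""Filter cascade: LOD, detection rule, normalization, outliers, sparsity."""

import numpy as np
import pandas as pd
import pytest

import plateqc as pq
from plateqc.qc import (RULE_DETECTION, RULE_ISTD, RULE_LOD, RULE_SPARSE,
                        compute_lod, detect_sample_outliers, detection_filter,
                        discard_sparse, normalize_to_istd)


def _frame(rows, compounds, conditions_reps):
    """Small helper: build values/meta frames from plain lists."""
    meta = pd.DataFrame([
        {"sample_id": f"{c}_r{r}", "sample_type": "SAMPLE", "condition": c,
         "replicate": r, "dilution_factor": np.nan}
        for c, r in conditions_reps])
    values = pd.DataFrame(rows, columns=compounds)
    return values, meta


@pytest.mark.parametrize("blanks, expected", [
    ([5000, 6000, 7000], 20000.0),    # 3 x 6000 = 18000 < floor
    ([10000, 20000, 30000], 60000.0),  # blank-derived LOD exceeds floor
    ([0, 0, 0], 20000.0),              # degenerate blanks fall to floor
])
def test_lod_is_max_of_blank_rule_and_floor(blanks, expected):
    frame = pd.DataFrame({"X": blanks})
    lods = compute_lod(frame, ["X"], pq.RunConfig())
    assert lods["X"] == expected


def test_lod_missing_blanks_degrade_to_floor_with_warning():
    warnings = []
    lods = compute_lod(pd.DataFrame(), ["X"], pq.RunConfig(), warnings)
    assert lods["X"] == 20000.0
    assert any("X" in w for w in warnings)


def test_lod_boundary_is_strict():
    values, meta = _frame([[20000.0], [20001.0], [25000.0]], ["X"],
                          [("A", 1), ("A", 2), ("A", 3)])
    audit = []
    out = pq.apply_lod_filter(values, meta, pd.Series({"X": 20000.0}), audit)
    assert np.isnan(out.loc[0, "X"])          # value == LOD is rejected
    assert out.loc[1, "X"] == 20001.0         # value > LOD survives
    assert [e["rule"] for e in audit] == [RULE_LOD]


@pytest.mark.parametrize("present, n_rep, kept", [
    (3, 5, True),    # 3 of 5 = 60%, valid
    (2, 5, False),   # 40%, dropped
    (3, 4, True),    # 75% after one replicate was removed upstream
])
def test_detection_rule_thresholds(present, n_rep, kept):
    rows = [[100.0] if r <= present else [np.nan] for r in range(1, n_rep + 1)]
    values, meta = _frame(rows, ["X"], [("A", r) for r in range(1, n_rep + 1)])
    audit = []
    out = detection_filter(values, meta, pq.RunConfig(), audit)
    assert out["X"].notna().sum() == (present if kept else 0)
    if not kept:
        assert len(audit) == present
        assert all(e["rule"] == RULE_DETECTION for e in audit)


def test_normalization_definition_and_istd_propagation(toy_panel):
    values, meta = _frame([[40000.0], [40000.0], [np.nan]], ["Ala"],
                          [("A", 1), ("A", 2), ("A", 3)])
    istd = pd.DataFrame({"IS_AA": [20000.0, 10000.0, 20000.0]})
    out = normalize_to_istd(values, istd, toy_panel, [], meta)
    assert out.loc[0, "Ala"] == 2.0
    # halving the IS doubles the normalized value in that injection
    assert out.loc[1, "Ala"] == 4.0
    assert np.isnan(out.loc[2, "Ala"])  # missing stays missing


def test_zero_istd_voids_injection_with_audit(toy_panel):
    values, meta = _frame([[40000.0]], ["Ala"], [("A", 1)])
    istd = pd.DataFrame({"IS_AA": [0.0]})
    audit = []
    out = normalize_to_istd(values, istd, toy_panel, audit, meta)
    assert np.isnan(out.loc[0, "Ala"])
    assert audit[0]["rule"] == RULE_ISTD


def test_outlier_bounds_arithmetic_with_raw_mad(toy_panel):
    # block sums (100, 101, 99, 100, 250): median 100, MAD 1,
    # raw-MAD bounds [97.5, 102.5] -> only the 250 replicate is removed
    sums = [100.0, 101.0, 99.0, 100.0, 250.0]
    values, meta = _frame([[s] for s in sums], ["Ala"],
                          [("A", r) for r in range(1, 6)])
    config = pq.RunConfig(mad_scale=1.0)
    records = detect_sample_outliers(values, meta, toy_panel, config)
    lc = [r for r in records if r["block"] == "LC"]
    assert lc[0]["lower"] == 97.5 and lc[0]["upper"] == 102.5
    assert [r["replicate"] for r in lc if r["removed"]] == [5]


def test_outlier_degenerate_all_equal_none_flagged(toy_panel):
    values, meta = _frame([[5.0]] * 5, ["Ala"],
                          [("A", r) for r in range(1, 6)])
    records = detect_sample_outliers(values, meta, toy_panel, pq.RunConfig())
    assert not any(r["flagged"] for r in records)


def test_outlier_removal_capped_at_min_retained_replicates(toy_panel):
    # two replicates far outside the bounds, but only one removal allowed
    sums = [100.0, 100.0, 100.5, 300.0, 500.0]
    values, meta = _frame([[s] for s in sums], ["Ala"],
                          [("A", r) for r in range(1, 6)])
    records = detect_sample_outliers(values, meta, toy_panel, pq.RunConfig())
    lc = [r for r in records if r["block"] == "LC"]
    removed = [r["replicate"] for r in lc if r["removed"]]
    flagged = [r["replicate"] for r in lc if r["flagged"]]
    assert removed == [5]                      # most extreme first
    assert set(flagged) == {4, 5}
    assert any(r.get("status") == "flagged_not_removed" for r in lc)


def test_outlier_detection_invariant_to_global_istd_scale(toy_dataset):
    qc_a = pq.run_qc(toy_dataset)
    scaled = pq.PlateDataset(toy_dataset.panel, toy_dataset.meta.copy(),
                             toy_dataset.values.copy(),
                             toy_dataset.istd * 3.0)
    qc_b = pq.run_qc(scaled)
    assert qc_a.removed_injections() == qc_b.removed_injections()


def test_sparse_discard_boundary():
    config = pq.RunConfig()
    rows = [[1.0, 1.0], [1.0, 1.0], [np.nan, 1.0], [np.nan, np.nan],
            [np.nan, np.nan]]
    values, meta = _frame(rows, ["X", "Y"], [("A", r) for r in range(1, 6)])
    audit = []
    out = discard_sparse(values, meta, config, audit)
    assert out["X"].notna().sum() == 0          # 2 values -> dropped
    assert out["Y"].notna().sum() == 3          # 3 values -> kept
    assert all(e["rule"] == RULE_SPARSE and e["compound"] == "X"
               for e in audit)


def test_clean_generous_plate_retains_everything(mini_panel):
    config = pq.ScenarioConfig(panel=mini_panel, conditions=["A", "B"],
                               default_mean=500_000.0, default_cv=0.05,
                               seed=11)
    ds, _ = pq.simulate_plate(config)
    qc = pq.run_qc(ds)
    for name in mini_panel.names:
        for cond in ("A", "B"):
            assert qc.detected(name, cond)


def test_everything_below_floor_rejects_all_with_complete_audit(mini_panel):
    config = pq.ScenarioConfig(
        panel=mini_panel, conditions=["A"],
        below_floor_compounds=frozenset(mini_panel.names),
        below_floor_mean=2_000.0, seed=5)
    ds, _ = pq.simulate_plate(config)
    qc = pq.run_qc(ds)
    assert qc.retained == {}
    n_input = int(ds.sample_values().notna().sum().sum())
    assert len(qc.rejected) == n_input


def test_ground_truth_below_floor_matches_lod_rejections(mini_panel):
    planted = frozenset(mini_panel.names[:3])
    config = pq.ScenarioConfig(panel=mini_panel, conditions=["A", "B"],
                               default_mean=500_000.0,
                               below_floor_compounds=planted,
                               below_floor_mean=3_000.0, seed=9)
    ds, truth = pq.simulate_plate(config)
    qc = pq.run_qc(ds)
    lod_rejected = {e["compound"] for e in qc.rejected
                    if e["rule"] == RULE_LOD}
    assert lod_rejected == set(truth.below_floor)


def test_conservation_retained_plus_rejected_equals_input(toy_qc, toy_dataset):
    n_input = int(toy_dataset.sample_values().notna().sum().sum())
    n_retained = sum(len(v) for v in toy_qc.retained.values())
    assert n_retained + len(toy_qc.rejected) == n_input


def test_raising_noise_floor_never_increases_retention(mini_panel):
    config = pq.ScenarioConfig(panel=mini_panel, conditions=["A", "B"],
                               true_mean={n: m for n, m in zip(
                                   mini_panel.names,
                                   [15e3, 30e3, 60e3, 120e3] * 2)},
                               seed=21)
    ds, _ = pq.simulate_plate(config)
    previous = None
    for floor in (10_000, 20_000, 40_000, 80_000, 200_000):
        qc = pq.run_qc(ds, pq.RunConfig(noise_floor=floor))
        count = len(qc.retained_compounds())
        if previous is not None:
            assert count <= previous
        previous = count


def test_sensitivity_drop_pushes_threshold_compounds_out(mini_panel):
    # a compound sitting just above the 20,000-count floor in one study
    # disappears when overall instrument response drops slightly
    name = mini_panel.names[0]
    base = dict(panel=mini_panel, conditions=["A"],
                true_mean={name: 23_000.0}, default_mean=500_000.0,
                default_cv=0.02, cv={name: 0.02}, seed=13)
    ds_full, _ = pq.simulate_plate(pq.ScenarioConfig(**base))
    ds_degraded, _ = pq.simulate_plate(
        pq.ScenarioConfig(**base, sensitivity=0.8))
    assert name in pq.run_qc(ds_full).retained_compounds()
    assert name not in pq.run_qc(ds_degraded).retained_compounds()


def test_plate_without_blanks_is_rejected(mini_panel):
    config = pq.ScenarioConfig(panel=mini_panel, conditions=["A"], seed=1)
    ds, _ = pq.simulate_plate(config)
    keep = ds.meta["sample_type"] != "BLANK_PBS"
    stripped = pq.PlateDataset(ds.panel, ds.meta[keep].reset_index(drop=True),
                               ds.values[keep].reset_index(drop=True),
                               ds.istd[keep].reset_index(drop=True))
    with pytest.raises(pq.PlateFormatError, match="blank"):
        pq.run_qc(stripped)
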