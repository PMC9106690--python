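"""RSD summaries and the rank-based Kruskal–Wallis / Tukey–Kramer tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import plateqc as pq
from plateqc.stats import MISSING_WORST


# ------------------------------------------------------------- RSD ------

@pytest.mark.parametrize("values, expected", [
    ((10, 10, 10), 0.0),
    ((8, 10, 12), 20.0),           # sd 2, mean 10
    ((8.5, 10, 11.5), 15.0),       # sd 1.5, mean 10: exactly at threshold
])
def test_compound_rsd_definition(values, expected):
    assert pq.compound_rsd(values) == pytest.approx(expected)


def test_rsd_undefined_for_nonpositive_mean():
    assert math.isnan(pq.compound_rsd([-5.0, 1.0, 1.0]))
    assert math.isnan(pq.compound_rsd([3.0]))


def test_threshold_comparison_is_strict(toy_qc):
    # an RSD of exactly 15.0 must not count as "below 15%"
    summary = pq.summarize(toy_qc)
    assert not (15.0 < summary.rsd_threshold_pct)
    n_below, n_det = summary.below_threshold[("LC", "B")]
    assert (n_below, n_det) == (4, 4)
    rsd15 = pq.compound_rsd((8.5, 10, 11.5))
    assert not (rsd15 < summary.rsd_threshold_pct)


def test_summary_is_pure_function_of_qc(toy_qc):
    a, b = pq.summarize(toy_qc), pq.summarize(toy_qc)
    pd.testing.assert_frame_equal(a.rsd, b.rsd)
    pd.testing.assert_frame_equal(a.detected_counts, b.detected_counts)
    assert a.below_threshold == b.below_threshold


def test_toy_fixture_rsd_cells(toy_qc):
    summary = pq.summarize(toy_qc)
    # hand arithmetic on the retained normalized values
    assert summary.rsd.loc["Val", "B"] == pytest.approx(100 * 0.5 / 3.5)
    assert summary.rsd.loc["PC_5", "A"] == pytest.approx(0.0)
    assert summary.rsd.loc["Ala", "A"] == pytest.approx(
        100 * math.sqrt(2.1875 / 3) / 10.125)


# ----------------------------------------------------------- ranking ----

def _metric(rows, conditions):
    return pd.DataFrame(rows, columns=conditions)


def test_rank_conditions_examples():
    metric = _metric([[19, 22, 13, 25, 9, 10]], list("abcdef"))
    ranks = pq.rank_conditions(metric)
    assert list(ranks.iloc[0]) == [4, 5, 3, 6, 1, 2]

    ties = pq.rank_conditions(_metric([[5, 5, 10]], list("abc")))
    assert list(ties.iloc[0]) == [1.5, 1.5, 3]

    missing = pq.rank_conditions(_metric([[7, np.nan, 9]], list("abc")))
    assert missing.iloc[0]["a"] == 1 and missing.iloc[0]["c"] == 2
    assert np.isnan(missing.iloc[0]["b"])


def test_rank_conditions_worst_rank_mode():
    metric = _metric([[7, np.nan, 9]], list("abc"))
    ranks = pq.rank_conditions(metric, missing=MISSING_WORST)
    assert list(ranks.iloc[0]) == [1, 3, 2]


def test_all_missing_compound_excluded():
    metric = _metric([[np.nan, np.nan], [1.0, 2.0]], list("ab"))
    ranks = pq.rank_conditions(metric)
    assert len(ranks) == 1


# ---------------------------------------------------- Kruskal–Wallis ----

def test_kw_identical_values_convention():
    result = pq.kruskal_wallis([[5, 5], [5, 5], [5, 5]])
    assert result.H == 0.0 and result.p == 1.0


def test_kw_closed_form_instance():
    result = pq.kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert result.H == pytest.approx(32 / 7, abs=1e-12)


def test_kw_matches_scipy_on_random_instances():
    rng = np.random.default_rng(42)
    for _ in range(30):
        k = rng.integers(2, 5)
        groups = [rng.integers(0, 8, size=rng.integers(3, 9)).astype(float)
                  for _ in range(k)]  # integer values force ties
        if all(np.all(g == groups[0][0]) for g in groups):
            continue
        ours = pq.kruskal_wallis(groups)
        h_ref, p_ref = sps.kruskal(*groups)
        assert ours.H == pytest.approx(h_ref, rel=1e-12)
        assert ours.p == pytest.approx(p_ref, rel=1e-12)


def test_kw_exact_p_matches_enumeration_oracle():
    groups = [[1.0, 5.0], [2.0, 6.0], [8.0, 9.0]]
    ours = pq.kruskal_wallis(groups, p_method="exact")
    # independent oracle: enumerate all assignments, H from scipy
    pooled = [v for g in groups for v in g]
    h_obs = sps.kruskal(*groups).statistic
    count = total = 0
    for combo1 in itertools.combinations(range(6), 2):
        rest = [i for i in range(6) if i not in combo1]
        for combo2 in itertools.combinations(rest, 2):
            combo3 = [i for i in rest if i not in combo2]
            parts = [[pooled[i] for i in c]
                     for c in (combo1, combo2, combo3)]
            total += 1
            if sps.kruskal(*parts).statistic >= h_obs - 1e-9:
                count += 1
    assert ours.p == pytest.approx(count / total, abs=1e-12)


def test_rank_then_kw_invariant_under_monotone_transform():
    rng = np.random.default_rng(0)
    metric = pd.DataFrame(rng.lognormal(0, 1, size=(25, 4)),
                          columns=list("abcd"))
    transformed = np.exp(metric / 10.0)  # strictly monotone map
    a = pq.compare_conditions(metric)
    b = pq.compare_conditions(transformed)
    assert a.H == pytest.approx(b.H, rel=1e-12)
    assert a.p == pytest.approx(b.p, rel=1e-12)


# ------------------------------------------------------ Tukey–Kramer ----

def test_tukey_identical_groups_not_significant():
    pairs = pq.tukey_kramer_on_ranks([[1, 2, 3], [1, 2, 3]])
    assert pairs[0].diff == 0.0 and not pairs[0].significant


def test_tukey_two_groups_equals_two_group_kw():
    # with k = 2 and infinite-df quantiles, q = sqrt(2) z, so the rank-based
    # Tukey–Kramer p equals the chi-square Kruskal–Wallis p exactly
    rng = np.random.default_rng(7)
    for _ in range(20):
        a = rng.normal(0, 1, size=rng.integers(3, 9))
        b = rng.normal(0.5, 1, size=rng.integers(3, 9))
        pair = pq.tukey_kramer_on_ranks([a, b])[0]
        kw = pq.kruskal_wallis([a, b])
        assert pair.p == pytest.approx(kw.p, rel=1e-9)


def test_tukey_raw_mode_matches_statsmodels():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    rng = np.random.default_rng(3)
    groups = [rng.normal(m, 1, size=6) for m in (0.0, 0.5, 2.0)]
    ours = pq.tukey_kramer_on_ranks(groups, use_ranks=False)
    data = np.concatenate(groups)
    labels = np.repeat([0, 1, 2], 6)
    ref = pairwise_tukeyhsd(data, labels)
    for our_pair, p_ref in zip(ours, ref.pvalues):
        assert our_pair.p == pytest.approx(p_ref, abs=1e-6)


def test_shifted_condition_detected_by_posthoc():
    rng = np.random.default_rng(123)
    hits = 0
    n_runs = 200
    for _ in range(n_runs):
        metric = pd.DataFrame(rng.lognormal(0, 0.3, size=(30, 4)),
                              columns=list("abcd"))
        metric["d"] *= 8.0  # one condition far worse than the rest
        result = pq.compare_conditions(metric)
        sig = [pair for (ci, cj), pair in result.posthoc.items()
               if "d" in (ci, cj)]
        if all(p.significant for p in sig):
            hits += 1
    assert hits / n_runs >= 0.95


def test_h_nonnegative_and_p_in_unit_interval():
    rng = np.random.default_rng(5)
    for _ in range(50):
        groups = [rng.normal(0, 1, size=rng.integers(2, 7))
                  for _ in range(int(rng.integers(2, 6)))]
        res = pq.kruskal_wallis(groups)
        assert res.H >= 0.0
        assert 0.0 <= res.p <= 1.0
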