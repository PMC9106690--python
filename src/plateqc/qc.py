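"""The QC filter cascade for kit plates.

Stages, in order:

1. ``compute_lod`` — per-compound limit of detection from PBS blanks:
   ``max(3 x median blank signal, 20,000 counts)``.
2. ``apply_lod_filter`` — values must strictly exceed the LOD; rejected
   values become missing (never zero).
3. ``detection_filter`` — a compound is valid in a condition only if it is
   present in at least 60% of that condition's replicates.
4. ``normalize_to_istd`` — each analyte divided by its mapped labelled
   internal standard, per injection.
5. ``detect_sample_outliers`` — per condition and per acquisition block
   (LC / FIA), replicate sums of normalized signals outside
   ``median +/- 2.5 x MAD`` flag the whole injection; removals are capped so
   that at least ``min_retained_replicates`` replicates survive.
6. detection re-check on the retained replicates (same 60% rule, smaller
   denominator).
7. ``discard_sparse`` — any (compound, condition) cell with fewer than 3
   surviving values is dropped.

Every removed datum is recorded exactly once in the audit trail with the
rule that removed it (rule ids: ``lod``, ``detection_60pct``,
``istd_missing``, ``outlier_mad``, ``sparse_lt3``).  Missing values are never
imputed; they are simply absent from sums, counts and RSDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import PlateFormatError
from .io import PlateDataset
from .panel import FIA, LC, Panel

RULE_LOD = "lod"
RULE_DETECTION = "detection_60pct"
RULE_ISTD = "istd_missing"
RULE_OUTLIER = "outlier_mad"
RULE_SPARSE = "sparse_lt3"


@dataclass
class QCResult:
    """Outcome of the full cascade plus a complete audit trail."""

    panel: Panel
    config: RunConfig
    lod: pd.Series
    #: final IS-normalized matrix over all SAMPLE injections (NaN = removed)
    normalized: pd.DataFrame
    sample_meta: pd.DataFrame
    #: (compound, condition) -> retained normalized values
    retained: dict[tuple[str, str], np.ndarray]
    rejected: list[dict] = field(default_factory=list)
    outliers: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def retained_compounds(self) -> list[str]:
        names = {c for (c, _), v in self.retained.items() if len(v)}
        return [c for c in self.panel.names if c in names]

    def detected(self, compound: str, condition: str) -> bool:
        return len(self.retained.get((compound, condition), ())) > 0

    def removed_injections(self) -> list[tuple[str, int]]:
        seen: dict[tuple[str, int], None] = {}
        for o in self.outliers:
            if o.get("removed"):
                seen.setdefault((o["condition"], o["replicate"]))
        return list(seen)


def _audit(entries: list[dict], rule: str, compound: str, meta_row: pd.Series,
           value: float, detail: str = "") -> None:
    entries.append({
        "rule": rule,
        "compound": compound,
        "sample_id": meta_row["sample_id"],
        "condition": meta_row["condition"],
        "replicate": int(meta_row["replicate"]),
        "value": float(value),
        "detail": detail,
    })


def compute_lod(blanks: pd.DataFrame, compounds: list[str],
                config: RunConfig,
                warnings: list[str] | None = None) -> pd.Series:
    """Per-compound LOD: ``max(multiplier x median(blanks), noise_floor)``.

    Compounds with no blank values degrade to the floor alone (logged).
    """
    lods = {}
    for name in compounds:
        vals = blanks[name].dropna() if name in blanks.columns else pd.Series(
            dtype=float)
        if vals.empty:
            if warnings is not None:
                warnings.append(f"no blank values for {name}; LOD = floor")
            lods[name] = config.noise_floor
        else:
            lods[name] = max(config.lod_blank_multiplier * float(vals.median()),
                             config.noise_floor)
    return pd.Series(lods, dtype=float)


def apply_lod_filter(values: pd.DataFrame, meta: pd.DataFrame,
                     lods: pd.Series,
                     audit: list[dict]) -> pd.DataFrame:
    """Reject values not strictly above the compound LOD (audit rule ``lod``)."""
    out = values.copy()
    for name in values.columns:
        lod = float(lods[name])
        col = values[name]
        reject = col.notna() & ~(col > lod)
        for i in values.index[reject]:
            _audit(audit, RULE_LOD, name, meta.loc[i], col[i],
                   f"value <= LOD {lod:g}")
        out.loc[reject, name] = np.nan
    return out


def detection_filter(values: pd.DataFrame, meta: pd.DataFrame,
                     config: RunConfig, audit: list[dict],
                     detail: str = "") -> pd.DataFrame:
    """Apply the 60%-of-replicates detection rule per (compound, condition).

    The denominator is the number of replicate rows present in ``meta`` for
    the condition, so re-running after outlier removal uses the retained
    replicate count.
    """
    out = values.copy()
    for condition, idx in meta.groupby("condition", sort=False).groups.items():
        n_rep = len(idx)
        block = values.loc[idx]
        frac = block.notna().sum() / n_rep
        for name in values.columns:
            if frac[name] > 0 and frac[name] < config.detection_fraction:
                present = block.index[block[name].notna()]
                for i in present:
                    _audit(audit, RULE_DETECTION, name, meta.loc[i],
                           block.loc[i, name],
                           detail or f"detected in {int(block[name].notna().sum())}"
                                     f"/{n_rep} replicates")
                out.loc[present, name] = np.nan
    return out


def normalize_to_istd(values: pd.DataFrame, istd: pd.DataFrame,
                      panel: Panel, audit: list[dict],
                      meta: pd.DataFrame | None = None) -> pd.DataFrame:
    """Divide each analyte by its mapped internal standard, per injection.

    Missing stays missing; a missing or non-positive IS signal voids that
    injection's values for the affected compounds (rule ``istd_missing``).
    """
    out = pd.DataFrame(index=values.index, columns=values.columns, dtype=float)
    for name in values.columns:
        is_id = panel.istd_of(name)
        if is_id in istd.columns:
            ref = istd[is_id]
        else:
            ref = pd.Series(np.nan, index=values.index)
        good = ref.notna() & (ref > 0)
        out[name] = np.where(good, values[name] / ref, np.nan)
        lost = values[name].notna() & ~good
        if meta is not None:
            for i in values.index[lost]:
                _audit(audit, RULE_ISTD, name, meta.loc[i],
                       values.loc[i, name], f"internal standard {is_id} "
                                            "missing or non-positive")
    return out


def _block_outliers(sums: pd.Series, config: RunConfig) -> pd.DataFrame:
    med = float(sums.median())
    mad = float((sums - med).abs().median())
    half_width = config.outlier_mad_multiplier * config.mad_scale * mad
    dev = (sums - med).abs()
    flagged = dev > half_width
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(mad > 0, dev / (config.mad_scale * mad),
                         np.where(dev > 0, np.inf, 0.0))
    return pd.DataFrame({
        "sum": sums, "median": med, "mad": mad,
        "lower": med - half_width, "upper": med + half_width,
        "flagged": flagged, "score": score,
    })


def detect_sample_outliers(normalized: pd.DataFrame, meta: pd.DataFrame,
                           panel: Panel, config: RunConfig,
                           warnings: list[str] | None = None) -> list[dict]:
    """Flag whole-sample outliers per condition from block sums.

    For each condition, the normalized signals are summed per replicate
    separately over the LC block and the FIA block (missing values are
    absent from the sum) — the two blocks are separate acquisitions of the
    same extract, so an aberrant injection is block-specific and removal
    voids only that block's values for the replicate.  Replicates whose sum
    falls outside ``median +/- multiplier x MAD`` are flagged.  At most
    ``n_replicates - min_retained_replicates`` replicates are removed per
    condition and block, most extreme first; additional flags are kept in
    the record as flagged-but-not-removed.
    """
    blocks = {LC: [c for c in normalized.columns
                   if panel.measurement_type_of(c) == LC],
              FIA: [c for c in normalized.columns
                    if panel.measurement_type_of(c) == FIA]}
    records: list[dict] = []
    for condition, idx in meta.groupby("condition", sort=False).groups.items():
        if len(idx) < 3:
            if warnings is not None:
                warnings.append(
                    f"condition {condition!r}: fewer than 3 replicates, "
                    "outlier detection skipped")
            continue
        cap = max(len(idx) - config.min_retained_replicates, 0)
        for block_name, cols in blocks.items():
            if not cols:
                continue
            sums = normalized.loc[idx, cols].sum(axis=1, skipna=True,
                                                 min_count=0)
            stats = _block_outliers(sums, config)
            block_recs = []
            for i in idx:
                rec = {
                    "condition": condition,
                    "replicate": int(meta.loc[i, "replicate"]),
                    "row": int(i),
                    "block": block_name,
                    "sum": float(stats.loc[i, "sum"]),
                    "lower": float(stats.loc[i, "lower"]),
                    "upper": float(stats.loc[i, "upper"]),
                    "flagged": bool(stats.loc[i, "flagged"]),
                    "score": float(stats.loc[i, "score"]),
                    "removed": False,
                }
                block_recs.append(rec)
            flagged = sorted((r for r in block_recs if r["flagged"]),
                             key=lambda r: r["score"], reverse=True)
            for rec in flagged[:cap]:
                rec["removed"] = True
            for rec in flagged[cap:]:
                rec["status"] = "flagged_not_removed"
            records.extend(block_recs)
    return records


def discard_sparse(values: pd.DataFrame, meta: pd.DataFrame,
                   config: RunConfig, audit: list[dict]) -> pd.DataFrame:
    """Drop (compound, condition) cells with fewer than the minimum values."""
    out = values.copy()
    for condition, idx in meta.groupby("condition", sort=False).groups.items():
        block = values.loc[idx]
        counts = block.notna().sum()
        for name in values.columns:
            n = int(counts[name])
            if 0 < n < config.min_values_per_condition:
                present = block.index[block[name].notna()]
                for i in present:
                    _audit(audit, RULE_SPARSE, name, meta.loc[i],
                           block.loc[i, name],
                           f"only {n} values in condition")
                out.loc[present, name] = np.nan
    return out


def run_qc(dataset: PlateDataset, config: RunConfig | None = None) -> QCResult:
    """Run the full filter cascade on a plate and return the audited result."""
    config = config or RunConfig()
    panel = dataset.panel
    blanks = dataset.blank_values()
    if blanks.empty:
        raise PlateFormatError("at least one PBS blank injection is required "
                               "for LOD computation")

    audit: list[dict] = []
    warnings: list[str] = []
    compounds = [c for c in dataset.values.columns]
    lods = compute_lod(blanks, compounds, config, warnings)

    meta = dataset.sample_meta().copy()
    values = dataset.sample_values().copy()
    istd = dataset.istd.loc[meta.index]

    values = apply_lod_filter(values, meta, lods, audit)
    values = detection_filter(values, meta, config, audit)
    normalized = normalize_to_istd(values, istd, panel, audit, meta)

    outlier_records = detect_sample_outliers(normalized, meta, panel, config,
                                             warnings)
    removed = {(r["row"], r["block"]) for r in outlier_records if r["removed"]}

    # the LC and FIA blocks are separate acquisitions: an outlier removal
    # voids one replicate's values in one block only, and the detection
    # re-check uses that block's retained replicate count as denominator
    final = pd.DataFrame(np.nan, index=meta.index, columns=normalized.columns)
    retained: dict[tuple[str, str], np.ndarray] = {}
    for block_name in (LC, FIA):
        cols = [c for c in normalized.columns
                if panel.measurement_type_of(c) == block_name]
        if not cols:
            continue
        rows_removed = sorted({r for (r, b) in removed if b == block_name})
        for i in rows_removed:
            row = normalized.loc[i, cols]
            for name in row.index[row.notna()]:
                _audit(audit, RULE_OUTLIER, name, meta.loc[i], row[name],
                       "sample outlier (block sum outside MAD bounds)")
        work_meta = meta.drop(index=rows_removed)
        work = normalized.loc[work_meta.index, cols]
        if config.recheck_detection:
            work = detection_filter(work, work_meta, config, audit)
        work = discard_sparse(work, work_meta, config, audit)
        final.loc[work.index, cols] = work
        for condition, idx in work_meta.groupby("condition",
                                                sort=False).groups.items():
            for name in cols:
                vals = work.loc[idx, name].dropna().to_numpy()
                if len(vals):
                    retained[(name, condition)] = vals
    return QCResult(panel=panel, config=config, lod=lods, normalized=final,
                    sample_meta=meta, retained=retained, rejected=audit,
                    outliers=outlier_records, warnings=warnings)
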