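"""Plate table input/output.

A plate export is a wide CSV/TSV with one row per injection.  Metadata columns
``sample_id``, ``sample_type``, ``condition``, ``replicate`` (and, for
dilution-series injections, ``dilution_factor``) are followed by one column
per compound (peak area for LC analytes, peak intensity for FIA analytes) and
one column per internal standard.  Empty cells are missing values — never
zeros; a measured zero is a real datum that the LOD filter will reject.

Vendor-software status annotation columns (``<compound>_status``) are accepted
and ignored: the pipeline applies its own detection logic instead of the
vendor's quantifiability flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .errors import PlateFormatError
from .panel import FIA, LC, Panel

if TYPE_CHECKING:  # pragma: no cover
    from .qc import QCResult
    from .stats import RepeatabilitySummary

SAMPLE = "SAMPLE"
BLANK_PBS = "BLANK_PBS"
POOLED_QC = "POOLED_QC"
CALIBRATION = "CALIBRATION"
DILUTION = "DILUTION"
SAMPLE_TYPES = (SAMPLE, BLANK_PBS, POOLED_QC, CALIBRATION, DILUTION)

META_COLUMNS = ("sample_id", "sample_type", "condition", "replicate",
                "dilution_factor")
_MANDATORY_META = ("sample_id", "sample_type", "condition", "replicate")


@dataclass
class PlateDataset:
    """Injections x compounds measurements plus per-injection metadata.

    ``meta``, ``values`` and ``istd`` share one integer index (injection
    order).  ``values`` holds compound signals (NaN = missing), ``istd`` the
    internal-standard signals.
    """

    panel: Panel
    meta: pd.DataFrame
    values: pd.DataFrame
    istd: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.meta.index.equals(self.values.index)
                and self.meta.index.equals(self.istd.index)):
            raise PlateFormatError("meta/values/istd index mismatch")
        samples = self.meta[self.meta["sample_type"] == SAMPLE]
        pairs = samples[["condition", "replicate"]]
        if pairs.duplicated().any():
            dup = pairs[pairs.duplicated()].iloc[0]
            raise PlateFormatError(
                f"duplicate (condition, replicate) among SAMPLE records: "
                f"({dup['condition']}, {dup['replicate']})"
            )

    @property
    def n_injections(self) -> int:
        return len(self.meta)

    def rows_of_type(self, sample_type: str) -> pd.Index:
        return self.meta.index[self.meta["sample_type"] == sample_type]

    def blank_values(self) -> pd.DataFrame:
        return self.values.loc[self.rows_of_type(BLANK_PBS)]

    def sample_values(self) -> pd.DataFrame:
        return self.values.loc[self.rows_of_type(SAMPLE)]

    def sample_meta(self) -> pd.DataFrame:
        return self.meta.loc[self.rows_of_type(SAMPLE)]

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.sample_meta()["condition"]:
            seen.setdefault(c)
        return list(seen)


def _detect_delimiter(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def read_plate(path: str | Path, panel: Panel) -> PlateDataset:
    """Read a wide plate table, auto-detecting comma vs tab delimiters.

    Unknown compound columns are reported in ``dataset.metadata
    ["ignored_columns"]`` and dropped.  Negative signals are format errors;
    empty cells become NaN.
    """
    path = Path(path)
    sep = _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, dtype=str).reset_index(drop=True)

    for col in _MANDATORY_META:
        if col not in raw.columns:
            raise PlateFormatError(f"missing mandatory metadata column {col!r}")
    if "dilution_factor" not in raw.columns:
        raw["dilution_factor"] = np.nan

    meta = pd.DataFrame({
        "sample_id": raw["sample_id"],
        "sample_type": raw["sample_type"],
        "condition": raw["condition"].fillna(""),
        "replicate": pd.to_numeric(raw["replicate"], errors="coerce"),
        "dilution_factor": pd.to_numeric(raw["dilution_factor"],
                                         errors="coerce"),
    })
    bad_type = ~meta["sample_type"].isin(SAMPLE_TYPES)
    if bad_type.any():
        i = int(np.flatnonzero(bad_type)[0])
        raise PlateFormatError(
            f"row {i}: unknown sample_type {meta.loc[i, 'sample_type']!r}"
        )
    is_dil = meta["sample_type"] == DILUTION
    if is_dil.any() and not (meta.loc[is_dil, "dilution_factor"] > 0).all():
        raise PlateFormatError("DILUTION records require a positive "
                               "dilution_factor")
    meta.loc[~is_dil, "dilution_factor"] = np.nan
    meta["replicate"] = meta["replicate"].astype("Int64")

    signal_cols = [c for c in raw.columns if c not in META_COLUMNS]
    compound_cols = [c for c in signal_cols if c in panel]
    istd_cols = [c for c in signal_cols if c in set(panel.istd_ids)]
    ignored = [c for c in signal_cols
               if c not in compound_cols and c not in istd_cols]

    def _numeric(cols: list[str]) -> pd.DataFrame:
        parsed = {}
        for c in cols:
            vals = pd.to_numeric(
                raw[c].replace("", np.nan), errors="coerce"
            )
            unparsed = vals.isna() & raw[c].notna() & (raw[c].str.strip() != "")
            if unparsed.any():
                i = int(np.flatnonzero(unparsed)[0])
                raise PlateFormatError(
                    f"row {i}, column {c!r}: non-numeric value "
                    f"{raw.loc[i, c]!r}"
                )
            neg = vals < 0
            if neg.any():
                i = int(np.flatnonzero(neg)[0])
                raise PlateFormatError(
                    f"row {i}, column {c!r}: negative signal {vals[i]}"
                )
            parsed[c] = vals.astype(float)
        if not parsed:
            return pd.DataFrame(index=raw.index)
        return pd.concat(parsed, axis=1)

    values = _numeric(compound_cols)
    istd = _numeric(istd_cols)
    return PlateDataset(panel, meta, values, istd,
                        metadata={"source": str(path),
                                  "ignored_columns": ignored})


def write_plate(dataset: PlateDataset, path: str | Path) -> Path:
    """Write a dataset back to a wide CSV (inverse of :func:`read_plate`)."""
    path = Path(path)
    out = pd.concat([dataset.meta, dataset.values, dataset.istd], axis=1)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)
    return path


def format_fraction(n: int, total: int) -> str:
    """Render an ``n/N (pct%)`` table cell.

    The percentage is rounded half away from zero to the nearest integer
    (158/366 -> ``"158/366 (43%)"``, 22/27 -> ``"22/27 (81%)"``).
    """
    if total < 0 or n < 0:
        raise ValueError("counts must be non-negative")
    if total == 0:
        return "0/0 (0%)"
    pct = (200 * n + total) // (2 * total)  # floor(100 n / N + 1/2), exact
    return f"{n}/{total} ({pct}%)"


def _detected_counts_table(summary: "RepeatabilitySummary",
                           panel: Panel) -> pd.DataFrame:
    counts = summary.detected_counts
    conds = list(counts.columns)
    rows = []
    for cls in counts.index:
        mtype = next(c.measurement_type for c in panel.classes if c.name == cls)
        rows.append([cls, mtype] + [int(counts.loc[cls, c]) for c in conds])
    frame = pd.DataFrame(rows, columns=["class", "measurement_type"] + conds)
    for mtype, label in ((LC, "Sum LC"), (FIA, "Sum FIA")):
        block = frame[frame["measurement_type"] == mtype]
        frame.loc[len(frame)] = [label, mtype] + list(
            block[conds].sum().astype(int))
    totals = frame[frame["class"].isin(["Sum LC", "Sum FIA"])][conds].sum()
    frame.loc[len(frame)] = ["Total", "LC+FIA"] + list(totals.astype(int))
    return frame


def _rsd_summary_table(summary: "RepeatabilitySummary") -> pd.DataFrame:
    conds = list(summary.median_rsd_by_type.columns)
    rows = []
    for mtype in summary.median_rsd_by_type.index:
        med = summary.median_rsd_by_type.loc[mtype]
        rows.append([mtype, "Median RSD [%]"]
                    + [("" if pd.isna(med[c]) else f"{med[c]:.0f}")
                       for c in conds])
        cells = []
        for c in conds:
            n_below, n_det = summary.below_threshold.get((mtype, c), (0, 0))
            cells.append(format_fraction(n_below, n_det))
        rows.append([mtype, "RSD < threshold"] + cells)
    return pd.DataFrame(rows, columns=["measurement_type", "criteria"] + conds)


def write_report(qc: "QCResult", summary: "RepeatabilitySummary",
                 outdir: str | Path) -> dict[str, Path]:
    """Write the full report file set for one pipeline run.

    Emits the filtered IS-normalized matrix, the detected-compound count
    table (classes x conditions with LC/FIA/total sums), the RSD summary
    (median RSD and below-threshold ``n/N (pct%)`` cells per measurement
    type), and a machine-readable JSON audit of every filter decision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = qc.panel

    paths = {
        "normalized_matrix": outdir / "filtered_normalized.csv",
        "detected_counts": outdir / "detected_counts.csv",
        "rsd_summary": outdir / "rsd_summary.csv",
        "audit": outdir / "audit.json",
    }
    matrix = qc.sample_meta.join(qc.normalized)
    matrix.to_csv(paths["normalized_matrix"], index=False)
    _detected_counts_table(summary, panel).to_csv(
        paths["detected_counts"], index=False)
    _rsd_summary_table(summary).to_csv(paths["rsd_summary"], index=False)

    audit = {
        "config": qc.config.to_dict(),
        "lod": {c: float(v) for c, v in qc.lod.items()},
        "rejected": qc.rejected,
        "outliers": qc.outliers,
        "warnings": qc.warnings,
    }
    paths["audit"].write_text(json.dumps(audit, indent=1, default=float))
    return paths
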