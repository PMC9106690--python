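"""Relative-quantification range assessment over a serial dilution ladder.

The lowest calibration standard is serially diluted (default ladder
1:1.2 … 1:100, 14 levels, three injections per level) and measured like an
unknown sample.  A compound supports relative quantification wherever an
increase in concentration is reflected by an increase in measured signal:
per compound we drop injections failing the LOD filter, average the
surviving replicates per level, and find the longest contiguous run of
levels — anchored at the least-diluted usable level — over which the level
means increase strictly with concentration and a straight-line fit of mean
response against relative concentration reaches R² ≥ 0.9.

Verdicts: ``QUANTIFIABLE_RELATIVE`` (the run covers every surviving level),
``PARTIAL_RANGE`` (a shorter run), ``EXCLUDED_BELOW_LOD`` (everything below
LOD, or fewer than four usable levels).  The numeric criterion (strict
monotonicity + R² threshold) is this package's reconstruction of the
qualitative published aim and is fully configurable.

The FIA analytes of the kit come with a single-point calibration only, so a
dilution ladder built from the kit standards cannot validate them; their
assessments are marked ``design_verified=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig
from .errors import ConfigError
from .panel import LC, Panel
from .io import DILUTION, PlateDataset

#: the 14-level serial dilution ladder applied to the lowest standard
DEFAULT_DILUTION_FACTORS: tuple[float, ...] = (
    1.2, 1.4, 1.6, 1.8, 2, 3, 5, 7.5, 10, 15, 20, 30, 50, 100)

QUANTIFIABLE_RELATIVE = "QUANTIFIABLE_RELATIVE"
PARTIAL_RANGE = "PARTIAL_RANGE"
EXCLUDED_BELOW_LOD = "EXCLUDED_BELOW_LOD"


def dilution_design(factors=DEFAULT_DILUTION_FACTORS) -> np.ndarray:
    """Relative concentration ladder: factor f -> 1/f.

    Factors must be >= 1 and strictly increasing.
    """
    arr = np.asarray(factors, dtype=float)
    if arr.size == 0:
        raise ConfigError("empty dilution ladder")
    if (arr < 1).any():
        raise ConfigError("dilution factors must be >= 1")
    if not (np.diff(arr) > 0).all():
        raise ConfigError("dilution factors must be strictly increasing")
    return 1.0 / arr


@dataclass
class DilutionAssessment:
    """Per-compound verdict over the dilution ladder."""

    compound: str
    #: dilution factors of the surviving levels, least-diluted first
    factors: list[float] = field(default_factory=list)
    relative_concentrations: list[float] = field(default_factory=list)
    mean_response: list[float] = field(default_factory=list)
    spearman_rho: float = float("nan")
    #: factors of the contiguous linear range (>= 2 levels, else empty)
    linear_range: list[float] = field(default_factory=list)
    verdict: str = EXCLUDED_BELOW_LOD
    excluded_reason: str = ""
    design_verified: bool = True


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float((resid ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def assess_dilution(dataset: PlateDataset, lods: pd.Series,
                    config: RunConfig | None = None,
                    r2_threshold: float = 0.9,
                    min_levels: int = 4,
                    min_replicates_per_level: int = 2
                    ) -> dict[str, DilutionAssessment]:
    """Assess every compound's relative-quantification range.

    Individual injections are LOD-filtered first; a level survives when at
    least ``min_replicates_per_level`` injections survive.  Compounds with
    fewer than ``min_levels`` surviving levels are excluded.
    """
    config = config or RunConfig()
    panel = dataset.panel
    rows = dataset.rows_of_type(DILUTION)
    if rows.empty:
        raise ConfigError("dataset has no DILUTION records")
    meta = dataset.meta.loc[rows]
    values = dataset.values.loc[rows]

    out: dict[str, DilutionAssessment] = {}
    for name in values.columns:
        assessment = DilutionAssessment(
            compound=name,
            design_verified=panel.measurement_type_of(name) == LC)
        lod = float(lods[name])
        col = values[name]
        surviving = col.notna() & (col > lod)

        factors, means = [], []
        for factor, idx in meta.groupby("dilution_factor",
                                        sort=True).groups.items():
            keep = [i for i in idx if surviving[i]]
            if len(keep) >= min_replicates_per_level:
                factors.append(float(factor))
                means.append(float(col[keep].mean()))
        if not factors:
            assessment.excluded_reason = "all levels below LOD"
            out[name] = assessment
            continue
        if len(factors) < min_levels:
            assessment.excluded_reason = "insufficient levels"
            assessment.factors = factors
            assessment.relative_concentrations = [1 / f for f in factors]
            assessment.mean_response = means
            out[name] = assessment
            continue

        conc = np.array([1.0 / f for f in factors])
        resp = np.array(means)
        assessment.factors = factors
        assessment.relative_concentrations = conc.tolist()
        assessment.mean_response = means
        rho = sps.spearmanr(conc, resp).statistic
        assessment.spearman_rho = float(rho)

        # walk from the least-diluted level toward higher dilution
        order = np.argsort(conc)[::-1]
        run = [order[0]]
        for nxt in order[1:]:
            if not resp[nxt] < resp[run[-1]]:
                break
            candidate = run + [nxt]
            if _r_squared(conc[candidate], resp[candidate]) < r2_threshold:
                break
            run = candidate
        n_design_levels = meta["dilution_factor"].nunique()
        if len(run) >= 2:
            assessment.linear_range = [factors[i] for i in run]
            # full relative quantification requires the whole design ladder:
            # a level lost to the LOD already narrows the usable range
            assessment.verdict = (QUANTIFIABLE_RELATIVE
                                  if len(run) == n_design_levels
                                  else PARTIAL_RANGE)
        else:
            assessment.linear_range = []
            assessment.verdict = PARTIAL_RANGE
            assessment.excluded_reason = "no monotone range"
        out[name] = assessment
    return out


def assessment_table(assessments: dict[str, DilutionAssessment]
                     ) -> pd.DataFrame:
    """Flatten assessments into a per-compound report table."""
    rows = []
    for name, a in assessments.items():
        rows.append({
            "compound": name,
            "verdict": a.verdict,
            "n_levels": len(a.factors),
            "spearman_rho": a.spearman_rho,
            "linear_range_min_factor": min(a.linear_range, default=np.nan),
            "linear_range_max_factor": max(a.linear_range, default=np.nan),
            "n_linear_levels": len(a.linear_range),
            "excluded_reason": a.excluded_reason,
            "design_verified": a.design_verified,
        })
    return pd.DataFrame(rows)
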