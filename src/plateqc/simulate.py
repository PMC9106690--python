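"""Synthetic plate generator.

Emulates a kit-style plate run: PBS blank injections, pooled-QC injections,
five biological replicates per experimental condition, and optionally a
serially diluted low-standard ladder.  Signals are log-normal with a
parameterization chosen so the configured ``cv`` equals the arithmetic
coefficient of variation exactly (``sigma^2 = ln(1 + cv^2)``, mean
preserved); intensities are therefore strictly positive and CV-recovery is
testable.  Blanks are log-normal around a configurable median so either LOD
branch (3x blank median vs the 20,000-count floor) can be made binding.

Planted truth — whole-sample outliers (a scalar multiplier on one
injection), compounds parked below the noise floor, and the true CV per
compound and condition — is returned alongside the data so every downstream
filter can be validated against ground truth.

One seed drives a single random stream; the draw order is fixed (blanks,
pooled QC, then samples condition by condition and replicate by replicate,
compounds before internal standards within an injection), so identical
seeds give bit-identical plates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dilution import DEFAULT_DILUTION_FACTORS
from .errors import ConfigError
from .io import (BLANK_PBS, DILUTION, POOLED_QC, SAMPLE, PlateDataset)
from .panel import Panel


@dataclass
class ScenarioConfig:
    """Study-design and noise parameters for one simulated plate."""

    panel: Panel
    conditions: list[str]
    replicates_per_condition: int = 5
    blank_count: int = 3
    pooled_qc_count: int = 5
    #: default true signal, counts (well above the 20,000-count floor)
    default_mean: float = 200_000.0
    #: per-compound overrides of the true mean
    true_mean: dict = field(default_factory=dict)
    default_cv: float = 0.10
    #: cv overrides; keys may be compound, class, (compound, condition) or
    #: (class, condition)
    cv: dict = field(default_factory=dict)
    #: per-condition multiplier on every compound mean
    condition_scale: dict = field(default_factory=dict)
    #: compounds whose true mean is forced to ``below_floor_mean``
    below_floor_compounds: frozenset = frozenset()
    below_floor_mean: float = 5_000.0
    #: (condition, replicate) -> whole-injection scale factor (!= 1)
    outlier_samples: dict = field(default_factory=dict)
    istd_mean: float = 100_000.0
    istd_cv: float = 0.05
    blank_median: float = 2_000.0
    blank_cv: float = 0.5
    #: global plate sensitivity multiplier (instrument response drift)
    sensitivity: float = 1.0
    dilution_factors: tuple = DEFAULT_DILUTION_FACTORS
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("at least one condition required")
        if self.replicates_per_condition < 3:
            raise ConfigError(
                "replicates_per_condition < 3: the pipeline could never "
                "retain anything (minimum 3 values per condition)")
        if self.blank_count < 3:
            raise ConfigError("blank_count must be >= 3")
        for value in [self.default_cv, self.istd_cv, self.blank_cv,
                      *self.cv.values()]:
            if not 0 < value < 2:
                raise ConfigError(f"cv {value} outside (0, 2)")
        for key, scale in self.outlier_samples.items():
            if scale <= 0 or scale == 1:
                raise ConfigError(
                    f"planted outlier {key} needs a positive scale != 1")
        if self.sensitivity <= 0:
            raise ConfigError("sensitivity must be positive")
        if any(f <= 0 for f in self.dilution_factors):
            raise ConfigError("non-positive dilution factor")

    # -- parameter resolution -------------------------------------------
    def mean_of(self, compound: str, condition: str | None = None) -> float:
        if compound in self.below_floor_compounds:
            base = self.below_floor_mean
        else:
            base = self.true_mean.get(compound, self.default_mean)
        if condition is not None:
            base *= self.condition_scale.get(condition, 1.0)
        return base

    def cv_of(self, compound: str, condition: str | None = None) -> float:
        cls = self.panel.class_of(compound)
        for key in ((compound, condition), (cls, condition), compound, cls):
            if key in self.cv:
                return self.cv[key]
        return self.default_cv


@dataclass
class GroundTruth:
    """What was planted, for validating the pipeline against."""

    true_mean: dict = field(default_factory=dict)        # compound -> counts
    true_cv: dict = field(default_factory=dict)          # (compound, condition)
    below_floor: frozenset = frozenset()
    outliers: dict = field(default_factory=dict)         # (cond, rep) -> scale


def _lognormal(rng: np.random.Generator, mean, cv, size=None) -> np.ndarray:
    """Log-normal draws with arithmetic mean ``mean`` and arithmetic CV ``cv``."""
    mean = np.asarray(mean, dtype=float)
    sigma2 = np.log1p(np.asarray(cv, dtype=float) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _blank_draw(rng: np.random.Generator, config: ScenarioConfig,
                size) -> np.ndarray:
    sigma = np.sqrt(np.log1p(config.blank_cv ** 2))
    return rng.lognormal(np.log(config.blank_median), sigma, size=size)


def simulate_plate(config: ScenarioConfig
                   ) -> tuple[PlateDataset, GroundTruth]:
    """Generate one plate: blanks, pooled QC and condition replicates."""
    rng = np.random.default_rng(config.seed)
    panel = config.panel
    names = panel.names
    istd_ids = panel.istd_ids
    s = config.sensitivity

    meta_rows: list[dict] = []
    value_rows: list[np.ndarray] = []
    istd_rows: list[np.ndarray] = []

    def istd_draw() -> np.ndarray:
        return s * _lognormal(rng, config.istd_mean, config.istd_cv,
                              size=len(istd_ids))

    for b in range(1, config.blank_count + 1):
        meta_rows.append({"sample_id": f"PBS_{b}", "sample_type": BLANK_PBS,
                          "condition": "", "replicate": b,
                          "dilution_factor": np.nan})
        value_rows.append(s * _blank_draw(rng, config, len(names)))
        istd_rows.append(istd_draw())

    qc_means = np.array([
        np.mean([config.mean_of(n, c) for c in config.conditions])
        for n in names])
    qc_cvs = np.array([config.cv_of(n) for n in names])
    for q in range(1, config.pooled_qc_count + 1):
        meta_rows.append({"sample_id": f"QC_{q}", "sample_type": POOLED_QC,
                          "condition": "", "replicate": q,
                          "dilution_factor": np.nan})
        value_rows.append(s * _lognormal(rng, qc_means, qc_cvs))
        istd_rows.append(istd_draw())

    truth = GroundTruth(below_floor=frozenset(config.below_floor_compounds),
                        outliers=dict(config.outlier_samples))
    for n in names:
        truth.true_mean[n] = config.mean_of(n)
    for condition in config.conditions:
        means = np.array([config.mean_of(n, condition) for n in names])
        cvs = np.array([config.cv_of(n, condition) for n in names])
        for n, c in zip(names, cvs):
            truth.true_cv[(n, condition)] = float(c)
        for rep in range(1, config.replicates_per_condition + 1):
            scale = config.outlier_samples.get((condition, rep), 1.0)
            meta_rows.append({
                "sample_id": f"{condition}_r{rep}", "sample_type": SAMPLE,
                "condition": condition, "replicate": rep,
                "dilution_factor": np.nan})
            value_rows.append(s * scale * _lognormal(rng, means, cvs))
            istd_rows.append(istd_draw())

    meta = pd.DataFrame(meta_rows)
    meta["replicate"] = meta["replicate"].astype("Int64")
    values = pd.DataFrame(value_rows, columns=names)
    istd = pd.DataFrame(istd_rows, columns=istd_ids)
    dataset = PlateDataset(panel, meta, values, istd,
                           metadata={"seed": config.seed,
                                     "sensitivity": s})
    return dataset, truth


def simulate_dilution_series(config: ScenarioConfig,
                             base_concentration_scale: float = 1.0,
                             replicates_per_level: int = 3) -> PlateDataset:
    """Simulate the serial dilution ladder of the lowest standard.

    For each dilution factor f, ``replicates_per_level`` injections are
    drawn with expected compound signal ``base/f`` plus an additive blank
    background draw, so heavily diluted levels bottom out at blank level
    rather than at zero.
    """
    if not config.dilution_factors:
        raise ConfigError("dilution_factors must be non-empty")
    rng = np.random.default_rng(
        None if config.seed is None else config.seed + 1)
    panel = config.panel
    names = panel.names
    istd_ids = panel.istd_ids
    s = config.sensitivity

    base = np.array([config.mean_of(n) for n in names]) \
        * base_concentration_scale
    cvs = np.array([config.cv_of(n) for n in names])

    meta_rows, value_rows, istd_rows = [], [], []
    for factor in config.dilution_factors:
        for rep in range(1, replicates_per_level + 1):
            signal = s * (_lognormal(rng, base / factor, cvs)
                          + _blank_draw(rng, config, len(names)))
            meta_rows.append({
                "sample_id": f"CAL1_1to{factor:g}_r{rep}",
                "sample_type": DILUTION, "condition": "CAL1_DILUTION",
                "replicate": rep, "dilution_factor": float(factor)})
            value_rows.append(signal)
            istd_rows.append(s * _lognormal(rng, config.istd_mean,
                                            config.istd_cv,
                                            size=len(istd_ids)))
    meta = pd.DataFrame(meta_rows)
    meta["replicate"] = meta["replicate"].astype("Int64")
    return PlateDataset(panel, meta, pd.DataFrame(value_rows, columns=names),
                        pd.DataFrame(istd_rows, columns=istd_ids),
                        metadata={"seed": config.seed, "series": "CAL1"})


def concat_plates(first: PlateDataset, second: PlateDataset) -> PlateDataset:
    """Stack two datasets sharing a panel (e.g. plate + dilution series)."""
    if first.panel is not second.panel:
        raise ConfigError("datasets must share a panel")
    meta = pd.concat([first.meta, second.meta], ignore_index=True)
    values = pd.concat([first.values, second.values], ignore_index=True)
    istd = pd.concat([first.istd, second.istd], ignore_index=True)
    return PlateDataset(first.panel, meta, values, istd,
                        metadata={**first.metadata, **second.metadata})
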