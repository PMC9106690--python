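"""Run configuration: every filter threshold of the QC cascade in one place.

Defaults follow the kit-validation protocol the pipeline implements: a
20,000-count noise floor, LOD = 3x the median blank signal, a 60% replicate
detection rule, median +/- 2.5 MAD sample-outlier bounds, at least 4 of 5
replicates retained, at least 3 values per compound and condition, and a 15%
RSD repeatability threshold.

``mad_scale`` is the MAD consistency constant (1.4826 makes the MAD estimate
the standard deviation under normality, as in the standard median +/- 2.5 MAD
outlier rule); set it to 1.0 for the raw, unscaled MAD.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass(frozen=True)
class RunConfig:
    noise_floor: float = 20_000.0
    lod_blank_multiplier: float = 3.0
    detection_fraction: float = 0.60
    outlier_mad_multiplier: float = 2.5
    mad_scale: float = 1.4826
    min_values_per_condition: int = 3
    min_retained_replicates: int = 4
    rsd_threshold_pct: float = 15.0
    alpha: float = 0.05
    recheck_detection: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        positive = (
            "noise_floor", "lod_blank_multiplier", "outlier_mad_multiplier",
            "mad_scale", "min_values_per_condition", "min_retained_replicates",
            "rsd_threshold_pct",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not 0 < self.detection_fraction <= 1:
            raise ConfigError("detection_fraction must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat key/value YAML file (optionally under a ``run:`` key)."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "run" in data and isinstance(data["run"], dict):
            data = data["run"]
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
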