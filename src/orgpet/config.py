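"""Run configuration: every tunable of the end-to-end pipeline, YAML round-trip.

Defaults reproduce the emulated acquisition settings: 35% duty cycle, 40%
SUVmax isocontour, 255 discretization bins, 4.07 mm voxels, 3.0 mm PSF,
15 mm cranio-caudal motion, and a 69-subject cohort with exponential
baseline hazard calibrated to a 40-week median survival and 20% censoring.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

__all__ = ["MotionConfig", "CohortConfig", "RunConfig"]


@dataclass(frozen=True)
class MotionConfig:
    """Breathing waveform parameters (means; per-subject values are jittered)."""

    amplitude_mm: float = 15.0
    period_s: float = 4.0
    exponent_n: int = 2
    duration_s: float = 60.0
    dt_s: float = 0.4
    drift_mm_per_min: float = 0.0
    cycle_jitter: float = 0.05
    motion_axis: int = 2


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort: size, survival model, planted feature effects."""

    n_subjects: int = 69
    lambda0_per_week: float = math.log(2) / 40.0
    censor_frac: float = 0.2
    # log-HR per 1 SD, keyed by feature name; applied to the planted reconstruction
    planted_effects: Dict[str, float] = field(
        default_factory=lambda: {"Sum Entropy.3": 0.5}
    )
    planted_reconstruction: str = "ORG"
    # between-subject variability of lesion geometry (SDs of the jitters)
    peak_suv_logsd: float = 0.2
    radius_sd_mm: float = 2.0
    amplitude_sd_mm: float = 3.0


@dataclass(frozen=True)
class RunConfig:
    duty: float = 0.35
    isocontour_fraction: float = 0.40
    n_bins: int = 255
    noise_scale: float = 12.5
    motion: MotionConfig = field(default_factory=MotionConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    output_dir: str = "orgpet_run"

    def validate(self) -> None:
        if not (0 < self.duty <= 1):
            raise ValueError("duty must lie in (0, 1]")
        if not (0 < self.isocontour_fraction < 1):
            raise ValueError("isocontour_fraction must lie in (0, 1)")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.cohort.n_subjects < 1:
            raise ValueError("cohort must have at least 1 subject")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "motion" in d and isinstance(d["motion"], dict):
            d["motion"] = MotionConfig(**d["motion"])
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig(**d["cohort"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
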