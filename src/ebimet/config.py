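"""Pipeline-wide configuration with the study's matching tolerances."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tolerances and thresholds shared across pipeline stages.

    Defaults: ±3 ppm accurate-mass matching, ±5 s co-elution, Pearson
    r > 0.9 time-trend filter, |r| > 0.4 association threshold for
    networking, run-QC windows of ±8 s and ±5 ppm, rule-chain enumeration
    depth 2 (one functionalization plus one conjugation), and any positive
    intensity counting as detected.
    """

    ppm_tol: float = 3.0
    rt_tol_s: float = 5.0
    r_time_min: float = 0.9
    r_assoc_min: float = 0.4
    qc_rt_s: float = 8.0
    qc_ppm: float = 5.0
    enumeration_depth: int = 2
    min_intensity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ppm_tol", "rt_tol_s", "r_time_min", "r_assoc_min",
                     "qc_rt_s", "qc_ppm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.enumeration_depth < 1:
            raise ValueError("enumeration_depth must be >= 1")
        if self.min_intensity < 0:
            raise ValueError("min_intensity must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load from a YAML mapping; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
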