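"""Analysis configuration: one YAML file, two sections.

The ``plate`` section controls blank subtraction and OD calibration; the
``growth`` section controls the window procedure for growth-feature
extraction. Every key has a default, so an empty file (or no file) is valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PlateConfig", "GrowthConfig", "Config", "load_config"]


@dataclass(frozen=True)
class PlateConfig:
    """Blank-subtraction and calibration settings."""

    blank_policy: str = "per-timepoint-mean"  # or "scalar-mean"
    clip_floor: float = 1e-4
    cal_linear: float = 1.0
    cal_cubic: float = 0.0
    cal_path_factor: float = 1.0
    cal_mode: str = "correct"  # or "invert"


@dataclass(frozen=True)
class GrowthConfig:
    """Window procedure and threshold settings for feature extraction.

    Rates are natural-log per hour throughout. ``min_window_h`` and
    ``r2_min`` implement the steepest-stable-slope rule (a window of at
    least 4 h whose log-linear fit reaches r² > 0.995); window lengths are
    capped at ``max_window_h`` unless ``full_enumeration`` is set.
    ``endpoint_rate_threshold`` (0.025 h⁻¹, i.e. a doubling time of 27.7 h)
    defines entry into stationary phase; ``diauxic_rate_threshold`` (0.07)
    defines the diauxic-shift rate dip used instead on rich medium.
    """

    min_window_h: float = 4.0
    max_window_h: float = 8.0
    full_enumeration: bool = False
    r2_min: float = 0.995
    endpoint_rate_threshold: float = 0.025
    diauxic_rate_threshold: float = 0.07
    baseline_points: int = 3
    lag_intercept: str = "baseline"  # or "time-axis"
    rich_medium_conditions: tuple[str, ...] = ()


@dataclass(frozen=True)
class Config:
    plate: PlateConfig = field(default_factory=PlateConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)


def _build(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    if "rich_medium_conditions" in mapping:
        mapping = dict(mapping)
        mapping["rich_medium_conditions"] = tuple(mapping["rich_medium_conditions"])
    return cls(**mapping)


def load_config(path: str | Path | None) -> Config:
    """Load a YAML config file; ``None`` yields all defaults."""
    if path is None:
        return Config()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"plate", "growth"}
    if unknown:
        raise ValueError(f"{path}: unknown config sections: {sorted(unknown)}")
    return Config(
        plate=_build(PlateConfig, raw.get("plate") or {}),
        growth=_build(GrowthConfig, raw.get("growth") or {}),
    )
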