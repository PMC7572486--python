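"""Pipeline configuration.

All numeric conventions of the analysis live here: the 5 m dive-detection
threshold, the >= 6 h foraging-trip and >= 10 min haul-out definitions, the
bottom-phase rule, zero-offset-correction window/quantile, the per-trip
KDE classifier settings, and the logistic prey-capture coefficients for
Australian fur seals (descent-rate slope 4.67, intercept -6.06).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the dive-analysis pipeline.

    Defaults reproduce the published analysis conventions for lactating
    Australian fur seals; every value is overridable from a flat YAML file.
    """

    #: Minimum depth (m) for a sample to count as diving; excludes surface
    #: activity and differing sensor precisions.
    dive_threshold: float = 5.0
    #: Minimum continuous wet period (h) for a candidate foraging trip.
    min_trip_duration: float = 6.0
    #: Minimum dry period (min) to count as a haul-out; shorter dry spells
    #: are treated as in-trip surface time (salt-water-switch drying).
    min_haulout_duration: float = 10.0
    #: Bottom phase = first..last sample deeper than this fraction of the
    #: dive's maximum depth.
    bottom_fraction: float = 0.8
    #: Zero-offset correction: centred moving window (s) and lower quantile.
    zoc_window: float = 10800.0
    zoc_quantile: float = 0.05
    #: Bandwidth rule for the per-trip Gaussian KDE of the weighted
    #: max-depth index ("silverman", "scott", or a float factor).
    kde_bandwidth_rule: str = "silverman"
    #: Minimum dives in a trip for KDE classification; below this the trip
    #: falls back to all-benthic with a flag.
    min_dives_for_kde: int = 10
    #: Mode prominence threshold as a fraction of the peak density.
    kde_prominence: float = 0.05
    #: Logistic prey-capture model: p = expit(coef * descent_rate + intercept).
    capture_coef_rate: float = 4.67
    capture_intercept: float = -6.06
    #: Dive boundary convention: "threshold" measures the dive between the
    #: 5 m crossings; "extended" includes one flanking sub-threshold sample
    #: on each side (approximates counting the 0-5 m transit).
    dive_boundary: str = "threshold"
    #: Denominator of the benthic dive rate: "dive_time" (sum of benthic
    #: dive durations, the printed definition) or "trip_time" (whole trip).
    dive_rate_denominator: str = "dive_time"
    #: Exclude trips truncated by the deployment edges from duration
    #: statistics (they are still reported, flagged partial).
    flag_partial_trips: bool = True

    def __post_init__(self) -> None:
        if self.dive_threshold <= 0 or self.min_trip_duration <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_haulout_duration <= 0:
            raise ValueError("min_haulout_duration must be positive")
        if not 0 < self.zoc_quantile <= 0.5:
            raise ValueError("zoc_quantile must lie in (0, 0.5]")
        if not 0 < self.bottom_fraction <= 1:
            raise ValueError("bottom_fraction must lie in (0, 1]")
        if self.dive_boundary not in ("threshold", "extended"):
            raise ValueError("dive_boundary must be 'threshold' or 'extended'")
        if self.dive_rate_denominator not in ("dive_time", "trip_time"):
            raise ValueError(
                "dive_rate_denominator must be 'dive_time' or 'trip_time'"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Read a flat key/value YAML file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
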