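"""Depth-record data model.

A :class:`DepthSeries` holds one deployment of a time-depth recorder (TDR):
a strictly increasing vector of sample times (epoch seconds, UTC), the
pressure-derived depth in metres (positive down; may be negative before
zero-offset correction), and an optional per-sample wet/dry flag from the
tag's salt-water switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DepthSeries"]


@dataclass
class DepthSeries:
    """One TDR deployment.

    Parameters
    ----------
    individual_id
        Deployment / animal identifier.
    t
        Sample times, epoch seconds (UTC). Strictly increasing, length >= 2.
        Nominal sampling interval is 1 or 5 s; gaps are permitted (tags that
        record only when wet stop sampling during haul-outs).
    depth
        Depth in metres, positive downward. Finite. Negative values are
        legal before zero-offset correction.
    wet
        Optional boolean wet/dry flag per sample. ``None`` if the tag does
        not report it; wet/dry is then inferred from recording gaps.
    """

    individual_id: str
    t: np.ndarray
    depth: np.ndarray
    wet: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.wet is not None:
            self.wet = np.asarray(self.wet, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.t.ndim != 1 or self.depth.ndim != 1:
            raise ValueError("t and depth must be 1-D arrays")
        if len(self.t) != len(self.depth):
            raise ValueError("t and depth must have the same length")
        if len(self.t) < 2:
            raise ValueError("a depth series needs at least 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            if dt[bad] == 0:
                raise ValueError(f"duplicate timestamp at sample {bad + 1}")
            raise ValueError(f"non-monotone timestamp at sample {bad + 1}")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depth contains non-finite values")
        if self.wet is not None and len(self.wet) != len(self.t):
            raise ValueError("wet flag length mismatch")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def nominal_interval(self) -> float:
        """Nominal sampling interval in seconds (median of time steps)."""
        return float(np.median(np.diff(self.t)))

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) sample time in epoch seconds."""
        return float(self.t[0]), float(self.t[-1])

    @property
    def duration(self) -> float:
        """Deployment span in seconds."""
        return float(self.t[-1] - self.t[0])

    def copy(self) -> "DepthSeries":
        return DepthSeries(
            self.individual_id,
            self.t.copy(),
            self.depth.copy(),
            None if self.wet is None else self.wet.copy(),
        )
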