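"""Zero-offset correction (ZOC) of depth traces.

Pressure sensors on archival tags drift slowly, so the "surface" reading
wanders away from 0 m. The correction estimates the per-sample offset as a
running lower quantile of depth over a centred time window — surface
intervals between dives guarantee that the lower tail of every window is
surface — smooths it with a running median, subtracts it, and clamps any
sample that corrects below 0 m to 0. The estimated offset curve is
returned for audit.

The quantile is evaluated on a coarse time grid (window/60) and linearly
interpolated to the samples; windows are time-based, so recording gaps
(tags that stop sampling when dry) are handled transparently.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import medfilt

from .series import DepthSeries

__all__ = ["zero_offset_correct"]


def _running_quantile(t: np.ndarray, depth: np.ndarray, window: float, quantile: float,
                      stride: float) -> tuple[np.ndarray, np.ndarray]:
    grid = np.arange(t[0], t[-1] + stride, stride)
    lo = np.searchsorted(t, grid - window / 2.0, side="left")
    hi = np.searchsorted(t, grid + window / 2.0, side="right")
    vals = np.empty(len(grid))
    for k in range(len(grid)):
        seg = depth[lo[k] : hi[k]]
        vals[k] = np.quantile(seg, quantile) if seg.size else np.nan
    # empty windows (long recording gaps): carry the neighbours across
    if np.any(np.isnan(vals)):
        ok = ~np.isnan(vals)
        vals = np.interp(grid, grid[ok], vals[ok])
    return grid, vals


def zero_offset_correct(
    series: DepthSeries,
    window: float = 10800.0,
    quantile: float = 0.05,
    smooth: float | None = None,
) -> tuple[DepthSeries, np.ndarray]:
    """Remove slow sensor drift so surface samples read ~0 m.

    Parameters
    ----------
    series
        Validated depth series (raw, possibly drifting).
    window
        Centred window length in seconds (>= 60). If it exceeds the
        deployment span, a single global offset is used (with a warning).
    quantile
        Lower quantile taken as the surface level within each window.
    smooth
        Span (s) of the median smoother applied to the offset curve;
        defaults to ``window / 3``.

    Returns
    -------
    (corrected, offset_curve)
        The corrected series (clamped at 0 m) and the per-sample offset
        that was subtracted.
    """
    if window < 60:
        raise ValueError("ZOC window must be at least 60 s")
    t, depth = series.t, series.depth
    span = t[-1] - t[0]
    if window > span:
        warnings.warn(
            "ZOC window exceeds deployment span; using a single global offset",
            stacklevel=2,
        )
        offset = np.full(len(t), np.quantile(depth, quantile))
    else:
        stride = max(series.nominal_interval, window / 60.0)
        grid, vals = _running_quantile(t, depth, window, quantile, stride)
        if smooth is None:
            smooth = window / 3.0
        k = int(round(smooth / stride))
        k = max(1, k) | 1  # odd kernel
        if k > 1 and k < len(vals):
            vals = medfilt(vals, kernel_size=k)
        offset = np.interp(t, grid, vals)
    corrected = np.maximum(depth - offset, 0.0)
    out = DepthSeries(
        series.individual_id,
        t.copy(),
        corrected,
        None if series.wet is None else series.wet.copy(),
    )
    return out, offset
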