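"""Tabular I/O for all pipeline artefacts.

One open dialect is used everywhere: comma-separated text with a header
row, UTC epoch-second timestamps, locale-independent numbers, and missing
values written as empty fields (missing is never 0 — an FTEI of 0 means
something). Depth-series files carry columns ``t``, ``depth_m`` and
optionally ``wet``; derived tables (dives, trips, haul-outs, covariates)
are plain :class:`pandas.DataFrame` round-trips of the same dialect.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .series import DepthSeries

__all__ = [
    "read_depth_series",
    "write_depth_series",
    "read_table",
    "write_table",
    "FormatError",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the tabular dialect."""


_NOMINAL_INTERVALS = (1.0, 5.0)


def read_depth_series(path: str | Path, individual_id: str | None = None) -> DepthSeries:
    """Read a depth-series table (columns ``t``, ``depth_m``[, ``wet``]).

    Timestamps must be strictly increasing epoch seconds; duplicates and
    non-monotone rows are rejected with the offending line number. A
    nominal sampling interval other than 1 or 5 s (+/-10%) triggers a
    warning, not an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse: {exc}") from exc
    for col in ("t", "depth_m"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    t = pd.to_numeric(df["t"], errors="coerce").to_numpy(dtype=float)
    depth = pd.to_numeric(df["depth_m"], errors="coerce").to_numpy(dtype=float)
    for name, arr in (("t", t), ("depth_m", depth)):
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            # +2: one for the header line, one for 1-based numbering
            raise FormatError(f"{path}: non-numeric {name} at line {bad[0] + 2}")
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        kind = "duplicate" if dt[bad[0]] == 0 else "non-monotone"
        raise FormatError(f"{path}: {kind} timestamp at line {bad[0] + 3}")
    wet = None
    if "wet" in df.columns:
        wet = df["wet"].astype(bool).to_numpy()
    interval = float(np.median(dt))
    if not any(abs(interval - nom) <= 0.1 * nom for nom in _NOMINAL_INTERVALS):
        warnings.warn(
            f"{path}: nominal sampling interval {interval:g} s is not 1 or 5 s",
            stacklevel=2,
        )
    if individual_id is None:
        individual_id = path.stem
    return DepthSeries(individual_id, t, depth, wet)


def write_depth_series(series: DepthSeries, path: str | Path) -> None:
    """Write a :class:`DepthSeries` in the standard dialect."""
    data = {"t": series.t, "depth_m": series.depth}
    if series.wet is not None:
        data["wet"] = series.wet.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


def write_table(records, path: str | Path) -> None:
    """Write a homogeneous record table (dives, trips, haul-outs, ...).

    ``records`` may be a DataFrame or a list of dicts/dataclass-likes.
    Missing values are written as empty fields. An empty record list still
    produces a header-only file when a DataFrame with columns is given.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    df.to_csv(path, index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    try:
        return pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
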