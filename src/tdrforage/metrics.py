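"""Per-trip foraging effort, success and efficiency indices.

For the benthic dives of a foraging trip with descent distance ``d_i``,
ascent distance ``a_i``, duration ``t_i`` (hours) and predicted capture
probability ``p_i``:

* benthic dive rate   ``b = sum(d_i + a_i) / sum(t_i)``   (m/h, effort)
* trip success index  ``FTSI = sum(p_i) / sum(t_i)``      (1/h)
* trip efficiency     ``FTEI = sum(p_i) / b``             (success per
  unit vertical effort)

plus the proportion of benthic dives (PBD), the proportion of at-sea time
spent diving, and the dive count N. Capture probabilities apply to benthic
dives only (the logistic model was validated on benthic dives). Undefined
indices (no benthic dives; b = 0) are missing values, never 0 — a zero
FTSI is a meaningful observation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dives import capture_probability

__all__ = [
    "benthic_dive_rate",
    "trip_ftsi",
    "trip_ftei",
    "trip_activity_metrics",
    "compute_trip_metrics",
    "metric_correlation_check",
]


def benthic_dive_rate(
    descent_distance,
    ascent_distance,
    duration_h,
    denominator: str = "dive_time",
    trip_duration_h: float | None = None,
) -> float:
    """Vertical distance travelled per hour over a trip's benthic dives.

    ``denominator="dive_time"`` divides by the summed benthic dive
    durations (the index's printed definition); ``"trip_time"`` divides by
    the whole trip duration instead (an alternative reading in which the
    rate is per hour at sea). Missing (NaN) if there are no benthic dives.
    """
    d = np.asarray(descent_distance, dtype=float)
    a = np.asarray(ascent_distance, dtype=float)
    t = np.asarray(duration_h, dtype=float)
    if d.size == 0:
        return np.nan
    vertical = float(np.sum(d + a))
    if denominator == "trip_time":
        if trip_duration_h is None:
            raise ValueError("trip_time denominator needs trip_duration_h")
        return vertical / trip_duration_h
    denom = float(np.sum(t))
    return vertical / denom if denom > 0 else np.nan


def trip_ftsi(p_capture, duration_h) -> float:
    """Summed capture probabilities per hour of benthic diving (1/h)."""
    p = np.asarray(p_capture, dtype=float)
    t = np.asarray(duration_h, dtype=float)
    if p.size == 0 or float(np.sum(t)) <= 0:
        return np.nan
    return float(np.sum(p) / np.sum(t))


def trip_ftei(p_capture, b: float) -> float:
    """Summed capture probabilities per unit benthic dive rate."""
    p = np.asarray(p_capture, dtype=float)
    if p.size == 0 or not np.isfinite(b) or b <= 0:
        return np.nan
    return float(np.sum(p) / b)


def trip_activity_metrics(dive_durations_s, labels, trip_duration_h: float):
    """(PBD, proportion of time diving, N) for one finalised trip."""
    durations = np.asarray(dive_durations_s, dtype=float)
    labels = np.asarray(labels, dtype=object)
    n = durations.size
    if n == 0:
        raise ValueError("a finalised trip has at least one dive")
    pbd = float((labels == "benthic").sum()) / n
    prop_diving = float(durations.sum()) / (trip_duration_h * 3600.0)
    return pbd, prop_diving, n


def compute_trip_metrics(
    trips: pd.DataFrame,
    dives: pd.DataFrame,
    capture_coef: float = 4.67,
    capture_intercept: float = -6.06,
    dive_rate_denominator: str = "dive_time",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Append b, FTSI, FTEI, PBD, prop_time_diving and N to the trip table.

    Capture probabilities are computed here for benthic dives with valid
    phases; dives with undefined phases (or zero-duration descents) are
    excluded from the rate indices but still count towards N and PBD.
    Returns ``(trips, dives)`` with the dives table carrying ``p_capture``.
    """
    trips = trips.copy()
    dives = dives.copy()
    usable = (
        (dives["label"] == "benthic")
        & dives["valid_phases"]
        & np.isfinite(dives["descent_rate"])
    )
    dives.loc[usable, "p_capture"] = capture_probability(
        dives.loc[usable, "descent_rate"].to_numpy(), capture_coef, capture_intercept
    )
    for col in ("b", "FTSI", "FTEI", "PBD", "prop_time_diving"):
        trips[col] = np.nan
    trips["N"] = pd.array([pd.NA] * len(trips), dtype="Int64")
    for i, trip in trips.iterrows():
        if trip["status"] != "foraging_trip":
            continue
        sub = dives[dives["trip_id"] == trip["trip_id"]]
        pbd, prop_diving, n = trip_activity_metrics(
            sub["duration_s"], sub["label"], trip["duration_h"]
        )
        ben = sub[(sub["label"] == "benthic") & sub["valid_phases"] & np.isfinite(sub["p_capture"])]
        b = benthic_dive_rate(
            ben["descent_distance"],
            ben["ascent_distance"],
            ben["duration_h"],
            denominator=dive_rate_denominator,
            trip_duration_h=trip["duration_h"],
        )
        trips.loc[i, ["b", "FTSI", "FTEI", "PBD", "prop_time_diving"]] = [
            b,
            trip_ftsi(ben["p_capture"], ben["duration_h"]),
            trip_ftei(ben["p_capture"], b),
            pbd,
            prop_diving,
        ]
        trips.loc[i, "N"] = n
    return trips, dives


def metric_correlation_check(trips: pd.DataFrame, dives: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r among the index building blocks, for audit.

    The blocks are the per-trip sums entering b, FTSI and FTEI: vertical
    distance ``sum(d_i + a_i)``, summed capture probability ``sum(p_i)``
    and summed benthic dive time ``sum(t_i)``. The published analysis
    reports these as weakly correlated (r < 0.3). Constant columns give
    undefined (NaN) correlations, reported as such.
    """
    rows = []
    for trip in trips.itertuples():
        if trip.status != "foraging_trip":
            continue
        ben = dives[
            (dives["trip_id"] == trip.trip_id)
            & (dives["label"] == "benthic")
            & dives["valid_phases"]
        ]
        rows.append(
            {
                "vertical_distance": (ben["descent_distance"] + ben["ascent_distance"]).sum(),
                "sum_p": ben["p_capture"].sum(),
                "sum_t": ben["duration_h"].sum(),
            }
        )
    blocks = pd.DataFrame(rows)
    if len(blocks) < 3:
        raise ValueError("correlation check needs at least 3 foraging trips")
    out = []
    cols = list(blocks.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            x, y = blocks[cols[i]], blocks[cols[j]]
            if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            out.append({"pair": f"{cols[i]}~{cols[j]}", "r": r, "n": len(blocks)})
    return pd.DataFrame(out)
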