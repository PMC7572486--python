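"""Haul-out and foraging-trip segmentation.

A deployment is partitioned into wet (at sea) and dry (hauled out)
intervals, either from the tag's salt-water-switch flag or — for tags
that only record when wet — from recording gaps. Dry spells shorter than
10 min are treated as in-trip surface time (salt-water switches dry out
during rafting); dry spells of >= 10 min are haul-outs. Wet periods of
>= 6 h containing at least one dive are candidate foraging trips; the
"at least one *benthic* dive" part of the trip definition can only be
applied after per-trip classification, so trips are finalised in a second
pass (:func:`finalise_trips`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .series import DepthSeries

__all__ = ["find_wet_dry", "build_haulouts", "build_trips", "finalise_trips"]


def find_wet_dry(series: DepthSeries, gap_factor: float = 2.0) -> pd.DataFrame:
    """Contiguous wet/dry intervals covering the deployment span.

    With a wet flag, intervals are maximal runs of the flag. Without one,
    any recording gap longer than ``gap_factor`` nominal sampling
    intervals is inferred to be dry. Intervals are half-open
    ``[start, end)``; the cover ends one sampling interval after the last
    sample.
    """
    dt = series.nominal_interval
    t = series.t
    rows = []
    if series.wet is not None:
        w = series.wet
        change = np.flatnonzero(np.diff(w.astype(np.int8))) + 1
        bounds = np.concatenate([[0], change, [len(w)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            start = t[a]
            end = t[b] if b < len(w) else t[-1] + dt
            rows.append({"start": start, "end": end, "state": "wet" if w[a] else "dry"})
    else:
        gaps = np.flatnonzero(np.diff(t) > gap_factor * dt)
        seg_start = t[0]
        for i in gaps:
            rows.append({"start": seg_start, "end": t[i] + dt, "state": "wet"})
            rows.append({"start": t[i] + dt, "end": t[i + 1], "state": "dry"})
            seg_start = t[i + 1]
        rows.append({"start": seg_start, "end": t[-1] + dt, "state": "wet"})
    df = pd.DataFrame(rows)
    df["duration_s"] = df["end"] - df["start"]
    return df


def build_haulouts(
    intervals: pd.DataFrame, min_haulout: float = 10.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split intervals into merged wet periods and haul-outs.

    Dry intervals of at least ``min_haulout`` minutes become haul-outs;
    shorter ones are merged into the surrounding wet period as surface
    time. Returns ``(wet_intervals, haulouts)``.
    """
    min_s = min_haulout * 60.0
    states = [
        "dry" if row.state == "dry" and row.duration_s >= min_s else "wet"
        for row in intervals.itertuples()
    ]
    merged: list[dict] = []
    for (_, row), state in zip(intervals.iterrows(), states):
        if merged and merged[-1]["state"] == state:
            merged[-1]["end"] = row["end"]
        else:
            merged.append({"start": row["start"], "end": row["end"], "state": state})
    df = pd.DataFrame(merged)
    df["duration_s"] = df["end"] - df["start"]
    wet = df[df["state"] == "wet"].drop(columns="state").reset_index(drop=True)
    dry = df[df["state"] == "dry"].drop(columns="state").reset_index(drop=True)
    dry["duration_min"] = dry["duration_s"] / 60.0
    return wet, dry


def build_trips(
    wet_intervals: pd.DataFrame,
    dives: pd.DataFrame,
    min_trip: float = 6.0,
    individual_id: str = "",
    span: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn wet intervals into candidate trips and assign dives to them.

    Wet periods of >= ``min_trip`` hours containing at least one dive are
    ``candidate`` trips; the rest are ``rejected`` with a reason. Every
    dive must fall inside exactly one wet interval (consistency error
    otherwise). Trips touching the deployment edges are flagged
    ``partial``. Returns ``(trips, dives-with-trip_id)``.
    """
    dives = dives.copy()
    dives["trip_id"] = pd.NA
    starts = wet_intervals["start"].to_numpy()
    ends = wet_intervals["end"].to_numpy()
    trip_rows = []
    n_dives_per = np.zeros(len(wet_intervals), dtype=int)
    if len(dives):
        idx = np.searchsorted(starts, dives["start"].to_numpy(), side="right") - 1
        ok = (idx >= 0) & (dives["end"].to_numpy() < ends[np.minimum(np.maximum(idx, 0), len(ends) - 1)])
        if not ok.all():
            bad = int(np.flatnonzero(~ok)[0])
            raise ValueError(
                f"dive starting at t={dives['start'].iloc[bad]:.0f} is not "
                "contained in any wet interval"
            )
        n_dives_per = np.bincount(idx, minlength=len(wet_intervals))
    for k, row in enumerate(wet_intervals.itertuples()):
        duration_h = (row.end - row.start) / 3600.0
        trip_id = f"{individual_id}-T{k + 1:03d}" if individual_id else f"T{k + 1:03d}"
        if duration_h < min_trip:
            status, reason = "rejected", "too_short"
        elif n_dives_per[k] == 0:
            status, reason = "rejected", "no_dives"
        else:
            status, reason = "candidate", ""
        partial = False
        if span is not None:
            partial = row.start <= span[0] or row.end >= span[1]
        trip_rows.append(
            {
                "trip_id": trip_id,
                "individual_id": individual_id,
                "start": row.start,
                "end": row.end,
                "duration_h": duration_h,
                "n_dives": int(n_dives_per[k]),
                "status": status,
                "reason": reason,
                "partial": partial,
            }
        )
    trips = pd.DataFrame(trip_rows)
    if len(dives):
        dives["trip_id"] = trips["trip_id"].to_numpy()[idx]
    return trips, dives


def finalise_trips(trips: pd.DataFrame, dives: pd.DataFrame) -> pd.DataFrame:
    """Apply the >= 1 benthic dive condition after classification.

    Candidates with at least one benthic-labelled dive become
    ``foraging_trip``; candidates without become ``rejected`` with reason
    ``no_benthic``. Every dive of every candidate must carry a label.
    """
    trips = trips.copy()
    for i, trip in trips.iterrows():
        if trip["status"] != "candidate":
            continue
        labels = dives.loc[dives["trip_id"] == trip["trip_id"], "label"]
        if (labels == "unclassified").any():
            raise ValueError(f"trip {trip['trip_id']} contains unlabelled dives")
        n_benthic = int((labels == "benthic").sum())
        trips.loc[i, "n_benthic"] = n_benthic
        if n_benthic >= 1:
            trips.loc[i, "status"] = "foraging_trip"
        else:
            trips.loc[i, "status"] = "rejected"
            trips.loc[i, "reason"] = "no_benthic"
    return trips
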