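"""End-to-end orchestration: raw depth trace -> model-ready tables.

``process_deployment`` runs the full chain on one deployment:
zero-offset correction -> dive detection and phase metrics -> wet/dry
segmentation -> haul-outs and candidate trips -> per-trip benthic/pelagic
classification -> trip finalisation -> capture probabilities and the
per-trip effort/success/efficiency indices. ``process_cohort`` maps it
over deployments and concatenates; ``run_all`` additionally simulates the
input cohort first (the synthetic study entry point).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .classify import classify_all
from .config import PipelineConfig
from .dives import detect_dives, summarise_dives
from .io import write_depth_series, write_table
from .metrics import compute_trip_metrics, metric_correlation_check
from .series import DepthSeries
from .simulate import SimConfig, simulate_cohort
from .trips import build_haulouts, build_trips, finalise_trips, find_wet_dry
from .zoc import zero_offset_correct

__all__ = ["process_deployment", "process_cohort", "run_all"]


def process_deployment(
    series: DepthSeries, config: PipelineConfig | None = None
) -> dict:
    """Run the whole pipeline on one deployment.

    Returns a dict with the corrected series, the ZOC offset curve, and
    the dives, trips, haul-outs and classification-audit tables.
    """
    config = config or PipelineConfig()
    corrected, offset = zero_offset_correct(
        series, window=config.zoc_window, quantile=config.zoc_quantile
    )
    segments = detect_dives(corrected, threshold=config.dive_threshold)
    dives = summarise_dives(
        corrected,
        segments,
        threshold=config.dive_threshold,
        bottom_fraction=config.bottom_fraction,
        boundary=config.dive_boundary,
    )
    intervals = find_wet_dry(corrected)
    wet, haulouts = build_haulouts(intervals, min_haulout=config.min_haulout_duration)
    dt = corrected.nominal_interval
    span = (corrected.t[0], corrected.t[-1] + dt)
    trips, dives = build_trips(
        wet,
        dives,
        min_trip=config.min_trip_duration,
        individual_id=series.individual_id,
        span=span,
    )
    dives, audit = classify_all(
        dives,
        trips,
        bandwidth_rule=config.kde_bandwidth_rule,
        min_dives=config.min_dives_for_kde,
        prominence=config.kde_prominence,
    )
    trips = finalise_trips(trips, dives)
    trips, dives = compute_trip_metrics(
        trips,
        dives,
        capture_coef=config.capture_coef_rate,
        capture_intercept=config.capture_intercept,
        dive_rate_denominator=config.dive_rate_denominator,
    )
    dives.insert(0, "individual_id", series.individual_id)
    haulouts.insert(0, "individual_id", series.individual_id)
    return {
        "corrected": corrected,
        "offset": offset,
        "dives": dives,
        "trips": trips,
        "haulouts": haulouts,
        "classification": audit,
    }


def process_cohort(
    deployments: list[DepthSeries], config: PipelineConfig | None = None
) -> dict:
    """Run the pipeline over a cohort and concatenate the tables."""
    results = [process_deployment(s, config) for s in deployments]
    out = {
        key: pd.concat([r[key] for r in results], ignore_index=True)
        for key in ("dives", "trips", "haulouts", "classification")
    }
    out["per_deployment"] = results
    if (out["trips"]["status"] == "foraging_trip").sum() >= 3:
        out["correlations"] = metric_correlation_check(out["trips"], out["dives"])
    return out


def run_all(
    sim_config: SimConfig,
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Simulate a cohort, process it, and (optionally) write all tables.

    The returned dict carries the processed tables plus the simulated
    series and ground truth under ``"simulated"``.
    """
    sims = simulate_cohort(sim_config)
    out = process_cohort([s for s, _ in sims], config)
    out["simulated"] = sims
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for series, truth in sims:
            write_depth_series(series, outdir / f"{series.individual_id}_depth.csv")
            write_table(truth.dives, outdir / f"{series.individual_id}_true_dives.csv")
            write_table(truth.trips, outdir / f"{series.individual_id}_true_trips.csv")
        for key in ("dives", "trips", "haulouts", "classification"):
            write_table(out[key], outdir / f"{key}.csv")
        if "correlations" in out:
            write_table(out["correlations"], outdir / "correlations.csv")
    return out
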