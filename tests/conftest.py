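"""Shared fixtures: simulated deployments, cohorts and constructed traces."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tdrforage import (
    DepthSeries,
    PipelineConfig,
    SimConfig,
    process_deployment,
    simulate_cohort,
    simulate_deployment,
)


def match_to_truth(detected: pd.DataFrame, truth_dives: pd.DataFrame):
    """Match detected dives to true dives by nearest start time.

    Returns (truth row indices, |start difference| in seconds).
    """
    ts = truth_dives["start"].to_numpy()
    ds = detected["start"].to_numpy()
    i = np.searchsorted(ts, ds)
    cand = np.clip(np.stack([i - 1, i]), 0, len(ts) - 1)
    dists = np.abs(ts[cand] - ds)
    best = cand[np.argmin(dists, axis=0), np.arange(len(ds))]
    return best, dists.min(axis=0)


def make_flag_series(
    segments: list[tuple[str, float, bool]],
    dt: float = 5.0,
    t0: float = 1275350400.0,
    dive_depth: float = 30.0,
    dive_period: float = 600.0,
) -> DepthSeries:
    """Construct a wet/dry-flagged trace from (state, seconds, with_dives).

    Wet segments with dives get a trapezoid dive (descend 4 samples, flat
    12, ascend 4, to ``dive_depth``) every ``dive_period`` seconds.
    """
    t_parts, d_parts, w_parts = [], [], []
    cur = t0
    profile = np.concatenate(
        [
            np.linspace(0, dive_depth, 5)[1:],
            np.full(12, dive_depth),
            np.linspace(dive_depth, 0, 5)[1:-1],
        ]
    )
    for state, dur_s, with_dives in segments:
        n = int(round(dur_s / dt))
        tt = cur + dt * np.arange(n)
        dd = np.zeros(n)
        if state == "wet" and with_dives:
            period = int(round(dive_period / dt))
            for s0 in range(period // 2, n - len(profile) - 1, period):
                dd[s0 : s0 + len(profile)] = profile
        t_parts.append(tt)
        d_parts.append(dd)
        w_parts.append(np.full(n, state == "wet"))
        cur += n * dt
    return DepthSeries(
        "fixture", np.concatenate(t_parts), np.concatenate(d_parts), np.concatenate(w_parts)
    )


# Noise- and drift-free 10-day deployment at 1 Hz with brief haul-outs,
# dense enough (~2,400 dives) to exercise detection against ground truth.
_DETECTION_CFG = SimConfig(
    seed=3,
    deployment_days=10.0,
    sampling_interval=1,
    haulout_duration_mean=2.0,
    haulout_duration_sd=0.5,
)


@pytest.fixture(scope="session")
def detection_run():
    series, truth = simulate_deployment(_DETECTION_CFG)
    result = process_deployment(series, PipelineConfig())
    return series, truth, result


def drift_scenario(kind: str, magnitude: float):
    cfg = SimConfig(
        seed=5,
        deployment_days=10.0,
        sampling_interval=1,
        haulout_duration_mean=2.0,
        haulout_duration_sd=0.5,
        drift_spec=(kind, magnitude),
    )
    series, truth = simulate_deployment(cfg)
    result = process_deployment(series, PipelineConfig())
    return series, truth, result


# 20-individual cohort at the default study conditions (78% benthic dives,
# ~244.5 dives/day, 6-day deployments at 5 s sampling).
COHORT_CFG = SimConfig(seed=11, n_individuals=20, deployment_days=6.0, sampling_interval=5)


@pytest.fixture(scope="session")
def cohort_run():
    sims = simulate_cohort(COHORT_CFG)
    results = [process_deployment(s, PipelineConfig()) for s, _ in sims]
    return sims, results
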