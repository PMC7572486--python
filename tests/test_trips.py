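"""Wet/dry segmentation, haul-out and trip building, two-pass finalisation."""

import numpy as np
import pandas as pd
import pytest

from tdrforage import (
    DepthSeries,
    PipelineConfig,
    build_haulouts,
    build_trips,
    finalise_trips,
    find_wet_dry,
    process_deployment,
    summarise_dives,
)
from conftest import make_flag_series

H = 3600.0


def _segment(series, min_haulout=10.0, min_trip=6.0):
    intervals = find_wet_dry(series)
    wet, haulouts = build_haulouts(intervals, min_haulout=min_haulout)
    dives = summarise_dives(series)
    return build_trips(wet, dives, min_trip=min_trip, individual_id="fixture") + (haulouts,)


class TestFindWetDry:
    def test_flagged_runs(self):
        series = make_flag_series([("wet", 8 * H, False), ("dry", 2 * H, False), ("wet", 8 * H, False)])
        iv = find_wet_dry(series)
        assert list(iv["state"]) == ["wet", "dry", "wet"]
        assert np.allclose(iv["duration_s"], [8 * H, 2 * H, 8 * H])

    def test_gap_inference(self):
        t = np.concatenate([np.arange(0, 3600, 5.0), np.arange(3600 + 1800, 3600 * 2 + 1800, 5.0)])
        series = DepthSeries("x", t, np.zeros_like(t))
        iv = find_wet_dry(series)
        dry = iv[iv["state"] == "dry"]
        assert len(dry) == 1
        assert dry["duration_s"].iloc[0] == pytest.approx(1800.0, abs=5.0)

    def test_matches_simulated_truth(self, detection_run):
        series, truth, _ = detection_run
        iv = find_wet_dry(series)
        wet = iv[iv["state"] == "wet"].reset_index(drop=True)
        assert len(wet) == len(truth.trips)
        dt = series.nominal_interval
        assert np.max(np.abs(wet["start"].to_numpy() - truth.trips["start"].to_numpy())) <= dt
        assert np.max(np.abs(wet["end"].to_numpy() - truth.trips["end"].to_numpy())) <= dt


class TestHaulouts:
    def test_nine_minutes_is_surface_time(self):
        series = make_flag_series([("wet", 7 * H, True), ("dry", 9 * 60, False), ("wet", 7 * H, True)])
        trips, _, haulouts = _segment(series)
        assert len(haulouts) == 0
        assert len(trips) == 1  # flanking wet periods merged
        assert trips["duration_h"].iloc[0] == pytest.approx(14 + 9 / 60, abs=0.01)

    def test_ten_minutes_is_a_haulout(self):
        series = make_flag_series([("wet", 7 * H, True), ("dry", 10 * 60, False), ("wet", 7 * H, True)])
        trips, _, haulouts = _segment(series)
        assert len(haulouts) == 1
        assert haulouts["duration_min"].iloc[0] == pytest.approx(10.0)
        assert len(trips) == 2

    def test_haulout_count_matches_truth(self, detection_run):
        series, truth, result = detection_run
        expected = truth.haulouts[
            (truth.haulouts["end"] - truth.haulouts["start"]) >= 600.0
        ]
        assert len(result["haulouts"]) == len(expected)


class TestBuildTrips:
    def test_short_wet_period_rejected(self):
        series = make_flag_series([("wet", 5.9 * H, True), ("dry", 2 * H, False)])
        trips, _, _ = _segment(series)
        assert trips["status"].iloc[0] == "rejected"
        assert trips["reason"].iloc[0] == "too_short"

    def test_six_hours_accepted(self):
        series = make_flag_series([("wet", 6.0 * H, True), ("dry", 2 * H, False)])
        trips, _, _ = _segment(series)
        assert trips["status"].iloc[0] == "candidate"

    def test_diveless_wet_period_rejected(self):
        series = make_flag_series([("wet", 48 * H, False), ("dry", 2 * H, False)])
        trips, _, _ = _segment(series)
        assert trips["status"].iloc[0] == "rejected"
        assert trips["reason"].iloc[0] == "no_dives"

    def test_uncontained_dive_is_a_consistency_error(self):
        series = make_flag_series([("wet", 8 * H, True), ("dry", 2 * H, False)])
        intervals = find_wet_dry(series)
        wet, _ = build_haulouts(intervals)
        dives = summarise_dives(series)
        dives.loc[0, "start"] = series.t[-1] + 9999.0
        dives.loc[0, "end"] = series.t[-1] + 10099.0
        with pytest.raises(ValueError, match="not.*contained|contained"):
            build_trips(wet, dives)

    def test_candidate_count_matches_truth(self, detection_run):
        _, truth, result = detection_run
        expected = truth.trips[
            ((truth.trips["end"] - truth.trips["start"]) >= 6 * H) & (truth.trips["n_dives"] >= 1)
        ]
        candidates = result["trips"][result["trips"]["status"] != "rejected"]
        assert len(candidates) == len(expected)

    def test_every_dive_in_exactly_one_trip(self, detection_run):
        _, _, result = detection_run
        dives = result["dives"]
        assert dives["trip_id"].notna().all()
        trips = result["trips"].set_index("trip_id")
        counts = dives.groupby("trip_id").size()
        assert (counts == trips.loc[counts.index, "n_dives"]).all()


class TestFinalise:
    def _trip_with_labels(self, labels):
        trips = pd.DataFrame(
            [{"trip_id": "T001", "status": "candidate", "reason": "", "duration_h": 12.0}]
        )
        dives = pd.DataFrame({"trip_id": ["T001"] * len(labels), "label": labels})
        return trips, dives

    def test_all_pelagic_rejected(self):
        trips, dives = self._trip_with_labels(["pelagic"] * 40)
        out = finalise_trips(trips, dives)
        assert out["status"].iloc[0] == "rejected"
        assert out["reason"].iloc[0] == "no_benthic"

    def test_single_benthic_suffices(self):
        trips, dives = self._trip_with_labels(["benthic"] + ["pelagic"] * 99)
        out = finalise_trips(trips, dives)
        assert out["status"].iloc[0] == "foraging_trip"
        assert out["n_benthic"].iloc[0] == 1

    def test_unlabelled_dives_rejected(self):
        trips, dives = self._trip_with_labels(["benthic", "unclassified"])
        with pytest.raises(ValueError, match="unlabelled"):
            finalise_trips(trips, dives)

    def test_nearly_all_true_trips_finalised(self, cohort_run):
        """At 78% benthic dives, essentially every real trip contains a
        benthic dive and survives finalisation."""
        sims, results = cohort_run
        n_true = sum(
            len(t.trips[(t.trips["end"] - t.trips["start"]) >= 6 * H]) for _, t in sims
        )
        n_final = sum((r["trips"]["status"] == "foraging_trip").sum() for r in results)
        assert n_final >= 0.99 * n_true


def test_raising_min_trip_duration_never_adds_trips(detection_run):
    series, _, _ = detection_run
    counts = []
    for min_trip in (2.0, 6.0, 12.0, 30.0, 80.0):
        cfg = PipelineConfig(min_trip_duration=min_trip)
        result = process_deployment(series, cfg)
        counts.append((result["trips"]["status"] == "foraging_trip").sum())
    assert all(a >= b for a, b in zip(counts, counts[1:]))
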