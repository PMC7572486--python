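"""Seasonal means, lags, standardisation and the model-ready join."""

import numpy as np
import pandas as pd
import pytest

from tdrforage import (
    assemble_covariate_table,
    join_trips,
    seasonal_mean,
    simulate_monthly_covariates,
    standardise_monthly,
)

LOCAL = ["SSTa", "chla", "wind_u", "SSHa"]
INDICES = ["SOI", "SAM", "IOD"]


@pytest.fixture(scope="module")
def monthly():
    return simulate_monthly_covariates(range(1995, 2019), seed=8)


def _series(values, variable="SSTa", year=2000):
    return pd.DataFrame(
        [
            {"variable": variable, "year": year + (m - 1) // 12, "month": (m - 1) % 12 + 1, "value": v}
            for m, v in enumerate(values, start=1)
        ]
    )


class TestStandardise:
    def test_zscore_moments(self):
        out = standardise_monthly(_series([1.0] * 12 + [2.0] * 12))
        v = out["value"]
        assert v.mean() == pytest.approx(0.0, abs=1e-12)
        assert v.std(ddof=1) == pytest.approx(1.0)

    def test_near_idempotent_on_standard_normal(self):
        rng = np.random.default_rng(0)
        raw = _series(rng.normal(0.0, 1.0, 264))
        out = standardise_monthly(raw)
        assert np.max(np.abs(out["value"].to_numpy() - raw["value"].to_numpy())) < 0.15

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            standardise_monthly(_series([1.0]))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            standardise_monthly(_series([3.0] * 24))

    def test_anomaly_removes_monthly_climatology(self):
        vals = list(range(1, 13)) * 3  # pure seasonal cycle
        out = standardise_monthly(_series(vals), method="anomaly")
        assert np.allclose(out["value"], 0.0)


class TestSeasonalMean:
    def test_winter_mean(self):
        s = _series([0, 0, 0, 0, 0, 1.0, 2.0, 3.0, 0, 0, 0, 0])
        assert seasonal_mean(s, "SSTa", "winter", 2000) == pytest.approx(2.0)

    def test_missing_month_propagates(self):
        s = _series([0, 0, 0, 0, 0, 1.0, 2.0, 3.0, 0, 0, 0, 0])
        s = s[s["month"] != 7]
        assert np.isnan(seasonal_mean(s, "SSTa", "winter", 2000))

    def test_annual_mean_of_constant(self):
        s = _series([4.2] * 12)
        assert seasonal_mean(s, "SSTa", "annual", 2000) == pytest.approx(4.2)


class TestAssemble:
    def test_lag_bookkeeping(self, monthly):
        table = assemble_covariate_table(monthly, range(2000, 2018), LOCAL, INDICES,
                                         standardise=None)
        spring_2010 = seasonal_mean(monthly, "SSTa", "spring", 2010)
        row_2012 = table.set_index("year").loc[2012]
        assert row_2012["SSTa_spring2"] == pytest.approx(spring_2010)

    def test_lag_identity_everywhere(self, monthly):
        """lag-k column of year y equals the lag-0 column of year y-k for
        every variable and k in {1, 2}."""
        years = range(1997, 2019)
        table = assemble_covariate_table(monthly, years, LOCAL, INDICES).set_index("year")
        spring = {
            (v, y): seasonal_mean(standardise_monthly(monthly), v, "spring", y)
            for v in LOCAL
            for y in range(1995, 2019)
        }
        for y in years:
            for v in LOCAL:
                for k in (1, 2):
                    assert table.loc[y, f"{v}_spring{k}"] == pytest.approx(spring[(v, y - k)])
            for v in INDICES:
                for k in (1, 2):
                    if y - k >= min(years):
                        assert table.loc[y, f"{v}_{k}"] == pytest.approx(table.loc[y - k, v])

    def test_insufficient_history_flagged_missing(self, monthly):
        table = assemble_covariate_table(monthly, range(1995, 1999), LOCAL, INDICES).set_index("year")
        assert np.isnan(table.loc[1995, "SSTa_spring1"])
        assert np.isnan(table.loc[1996, "SSTa_spring2"])
        assert bool(table.loc[1995, "any_missing"])
        assert not bool(table.loc[1998, "any_missing"])

    def test_equals_brute_force_recomputation(self, monthly):
        """The assembled table matches an independent plain-loop oracle."""
        years = list(range(1997, 2019))
        table = assemble_covariate_table(monthly, years, LOCAL, INDICES).set_index("year")
        std = standardise_monthly(monthly)
        lookup = {
            (r.variable, r.year, r.month): r.value for r in std.itertuples()
        }

        def mean_over(var, year, months):
            vals = [lookup.get((var, year, m), np.nan) for m in months]
            return float(np.mean(vals))

        for y in years:
            for v in LOCAL:
                np.testing.assert_allclose(table.loc[y, f"{v}_winter"], mean_over(v, y, (6, 7, 8)))
                np.testing.assert_allclose(
                    table.loc[y, f"{v}_spring1"], mean_over(v, y - 1, (9, 10, 11))
                )
                np.testing.assert_allclose(
                    table.loc[y, f"{v}_spring2"], mean_over(v, y - 2, (9, 10, 11))
                )
            for v in INDICES:
                for k, col in ((0, v), (1, f"{v}_1"), (2, f"{v}_2")):
                    np.testing.assert_allclose(
                        table.loc[y, col], mean_over(v, y - k, tuple(range(1, 13)))
                    )


class TestJoin:
    def test_join_preserves_trip_count_and_assigns_years(self, monthly):
        table = assemble_covariate_table(monthly, range(2009, 2012), LOCAL, INDICES)
        trips = pd.DataFrame(
            {
                # 2010-06-15 and 2011-01-02 UTC
                "trip_id": ["a", "b"],
                "start": [1276560000.0, 1293926400.0],
                "FTSI": [10.0, 12.0],
            }
        )
        joined = join_trips(trips, table)
        assert len(joined) == len(trips)
        assert list(joined["year"]) == [2010, 2011]
        assert joined["SSTa_winter"].notna().all()

    def test_missing_year_flagged(self, monthly):
        table = assemble_covariate_table(monthly, range(2009, 2011), LOCAL, INDICES)
        trips = pd.DataFrame({"trip_id": ["a"], "start": [631152000.0]})  # 1990
        joined = join_trips(trips, table)
        assert len(joined) == 1
        assert bool(joined["any_missing"].iloc[0])
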