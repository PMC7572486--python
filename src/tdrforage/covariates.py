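"""Seasonal, lagged environmental covariate tables.

Consumes tidy monthly series (``variable, year, month, value``) of local
oceanographic variables (e.g. SSTa, chl-a, zonal wind, SSHa) and
large-scale climate indices (SOI, SAM, IOD), and builds one row per study
year with:

* austral winter (Jun-Aug) means of each local variable for that year,
* austral spring (Sep-Nov) means of each local variable lagged 1 and
  2 years (prey spawn in spring; recruitment effects surface later),
* annual means of each large-scale index at lags 0, 1 and 2 years.

Monthly values are standardised per variable over the full study period
before aggregation (z-scores by default; subtraction of the monthly
climatology is available as an option). Missing months propagate to
missing seasonal means, which propagate to flagged rows — never silently
to zeros. The assembled table joins to trips by the trip's starting
calendar year, yielding the model-ready table that mixed-model analyses
consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "standardise_monthly",
    "seasonal_mean",
    "assemble_covariate_table",
    "join_trips",
    "SEASONS",
]

SEASONS = {
    "winter": (6, 7, 8),  # austral winter: June-August
    "spring": (9, 10, 11),  # austral spring: September-November
    "annual": tuple(range(1, 13)),
}


def _check_monthly(series: pd.DataFrame) -> None:
    required = {"variable", "year", "month", "value"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"monthly series missing columns {sorted(missing)}")
    if series["month"].min() < 1 or series["month"].max() > 12:
        raise ValueError("months must lie in 1..12")
    if series.duplicated(["variable", "year", "month"]).any():
        raise ValueError("duplicate (variable, year, month) entries")


def standardise_monthly(series: pd.DataFrame, method: str = "zscore") -> pd.DataFrame:
    """Standardise each variable's monthly values over the study period.

    ``zscore`` maps values to (v - mean) / sd per variable; ``anomaly``
    removes each variable's monthly climatology (mean of that calendar
    month) without rescaling. Zero variance or fewer than two values per
    variable is an error.
    """
    _check_monthly(series)
    out = series.copy()
    for var, grp in series.groupby("variable"):
        v = grp["value"].to_numpy(dtype=float)
        if len(v) < 2:
            raise ValueError(f"{var}: need at least 2 monthly values")
        if method == "zscore":
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"{var}: zero variance, cannot standardise")
            out.loc[grp.index, "value"] = (v - v.mean()) / sd
        elif method == "anomaly":
            clim = grp.groupby("month")["value"].transform("mean")
            out.loc[grp.index, "value"] = grp["value"] - clim
        else:
            raise ValueError(f"unknown standardisation method {method!r}")
    return out


def seasonal_mean(series: pd.DataFrame, variable: str, season: str, year: int) -> float:
    """Mean of one variable over one season of one year.

    All of the season's months must be present; otherwise NaN (missing
    propagates, it does not become 0).
    """
    months = SEASONS[season]
    sub = series[
        (series["variable"] == variable)
        & (series["year"] == year)
        & (series["month"].isin(months))
    ]
    if len(sub) < len(months):
        return np.nan
    return float(sub["value"].mean())


def assemble_covariate_table(
    monthly: pd.DataFrame,
    years: range | list[int],
    local_vars: list[str],
    index_vars: list[str],
    standardise: str | None = "zscore",
) -> pd.DataFrame:
    """One covariate row per study year.

    Columns: ``{v}_winter``, ``{v}_spring1``, ``{v}_spring2`` for each
    local variable; ``{i}``, ``{i}_1``, ``{i}_2`` (annual means at lag 0,
    1, 2 years) for each large-scale index; plus ``any_missing`` flagging
    rows with insufficient upstream history for a requested lag.
    """
    _check_monthly(monthly)
    if standardise is not None:
        monthly = standardise_monthly(monthly, method=standardise)
    rows = []
    for year in years:
        row: dict = {"year": int(year)}
        for v in local_vars:
            row[f"{v}_winter"] = seasonal_mean(monthly, v, "winter", year)
            row[f"{v}_spring1"] = seasonal_mean(monthly, v, "spring", year - 1)
            row[f"{v}_spring2"] = seasonal_mean(monthly, v, "spring", year - 2)
        for v in index_vars:
            row[v] = seasonal_mean(monthly, v, "annual", year)
            row[f"{v}_1"] = seasonal_mean(monthly, v, "annual", year - 1)
            row[f"{v}_2"] = seasonal_mean(monthly, v, "annual", year - 2)
        rows.append(row)
    table = pd.DataFrame(rows)
    value_cols = [c for c in table.columns if c != "year"]
    table["any_missing"] = table[value_cols].isna().any(axis=1)
    return table


def join_trips(trips: pd.DataFrame, table: pd.DataFrame) -> pd.DataFrame:
    """Join the yearly covariate table onto trips by trip start year.

    Trip start times are UTC epoch seconds; the trip's calendar year keys
    the join. The trip count is unchanged (left join); trips whose year is
    absent from the table get missing covariates and are flagged.
    """
    trips = trips.copy()
    trips["year"] = (
        pd.to_datetime(trips["start"], unit="s", utc=True).dt.year.astype(int)
    )
    joined = trips.merge(table, on="year", how="left", validate="many_to_one")
    if "any_missing" in joined.columns:
        joined["any_missing"] = (
            joined["any_missing"].astype("boolean").fillna(True).astype(bool)
        )
    return joined
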