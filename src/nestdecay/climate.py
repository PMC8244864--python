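"""Daily climate records and the per-nest climate covariates.

The field protocol records rainfall with a single gauge read twice per day:
the 18:00 reading covers the daytime intervals a (06-10), b (10-14) and
c (14-18); the next morning's 06:00 reading covers the night interval
d (18:00-06:00).  Each calendar-day row carries the reading covering *its
own* night, so a single row suffices to test the storm definition.  Weather
is coded per interval as rain / sun / clouds.

A *storm* is >= 20 mm of rain concentrated in a single evening-or-night
interval (c or d) of a day with no rain coded in any other interval.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .core import NestAge, NestRecord, ValidationError

__all__ = [
    "CLIMATE_COLUMNS",
    "read_climate_table",
    "validate_climate",
    "detect_storm",
    "storm_days",
    "nest_climate",
    "nest_climate_table",
    "aggregate_climate",
]

CLIMATE_COLUMNS = [
    "date",
    "rain_day_mm",
    "rain_night_mm",
    "weather_a",
    "weather_b",
    "weather_c",
    "weather_d",
    "tmin_c",
    "tmax_c",
]

WEATHER_CODES = ("rain", "sun", "clouds")
INTERVALS = ("a", "b", "c", "d")


def read_climate_table(path) -> pd.DataFrame:
    """Read and validate a ``climate.csv`` daily table."""
    df = pd.read_csv(path, parse_dates=["date"])
    df["date"] = df["date"].dt.date
    return validate_climate(df)


def validate_climate(df: pd.DataFrame) -> pd.DataFrame:
    for col in CLIMATE_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"missing required climate column {col!r}")
    for col in ("rain_day_mm", "rain_night_mm"):
        if (df[col] < 0).any():
            raise ValidationError(f"negative rain reading in {col}")
    if (df["tmax_c"] < df["tmin_c"]).any():
        raise ValidationError("tmax_c < tmin_c on some day")
    for col in ("weather_a", "weather_b", "weather_c", "weather_d"):
        bad = ~df[col].isin(WEATHER_CODES)
        if bad.any():
            raise ValidationError(f"unknown weather code in {col}: "
                                  f"{df.loc[bad, col].iloc[0]!r}")
    any_rain = (df["rain_day_mm"] > 0) | (df["rain_night_mm"] > 0)
    coded = (df[["weather_a", "weather_b", "weather_c", "weather_d"]] == "rain").any(axis=1)
    if (any_rain & ~coded).any():
        raise ValidationError("positive gauge reading on a day with no interval "
                              "coded rain")
    return df


def detect_storm(day, threshold_mm: float = 20.0) -> int:
    """1 iff *day* satisfies the storm definition, else 0.

    Exactly one of the four intervals is coded rain, that interval is the
    evening (c) or night (d) one, and the gauge reading covering it is at
    least ``threshold_mm``.  Morning/midday bursts and multi-interval rain
    days are not storms; temperatures are irrelevant.
    """
    rain_flags = [day[f"weather_{iv}"] == "rain" for iv in INTERVALS]
    if sum(rain_flags) != 1:
        return 0
    if rain_flags[2]:  # interval c, covered by the 18:00 (daytime) reading
        return int(day["rain_day_mm"] >= threshold_mm)
    if rain_flags[3]:  # interval d, covered by the next morning's reading
        return int(day["rain_night_mm"] >= threshold_mm)
    return 0


def storm_days(climate: pd.DataFrame, threshold_mm: float = 20.0) -> pd.Series:
    """Vectorized :func:`detect_storm` over a climate table (index-aligned
    0/1 Series)."""
    rain = climate[[f"weather_{iv}" for iv in INTERVALS]].to_numpy() == "rain"
    n_rain = rain.sum(axis=1)
    only_c = (n_rain == 1) & rain[:, 2]
    only_d = (n_rain == 1) & rain[:, 3]
    hit = (only_c & (climate["rain_day_mm"].to_numpy() >= threshold_mm)) | \
          (only_d & (climate["rain_night_mm"].to_numpy() >= threshold_mm))
    return pd.Series(hit.astype(int), index=climate.index, name="storm")


def _lifetime_window(nest: NestRecord, age: NestAge) -> tuple[dt.date, dt.date]:
    # [construction, construction + age_days - 1]: inclusive of the
    # construction day, exclusive of the day the nest was found decayed,
    # so its length in days equals the observed age.
    start = nest.construction_date
    end = start + dt.timedelta(days=age.age_days - 1)
    return start, end


def nest_climate(nest: NestRecord, age: NestAge, climate: pd.DataFrame,
                 threshold_mm: float = 20.0) -> dict:
    """Climate covariates for one nest.

    ``W_avg``: mean daily rainfall (day + night readings) over the nest's
    lifetime window; ``S_avg``: storm days / window length; ``R``: was rain
    coded in interval c (14:00-18:00) on the construction day; ``T``: that
    day's minimum temperature; ``D``: its max - min temperature.
    """
    start, end = _lifetime_window(nest, age)
    idx = climate.set_index("date") if climate.index.name != "date" else climate
    days = pd.date_range(start, end, freq="D").date
    missing = [d for d in days if d not in idx.index]
    if missing:
        raise ValidationError(
            f"nest {nest.nest_id}: climate gap inside lifetime window, "
            f"missing dates {missing[:5]}{'...' if len(missing) > 5 else ''}")
    window = idx.loc[list(days)]
    n_days = len(days)
    total_rain = float(window["rain_day_mm"].sum() + window["rain_night_mm"].sum())
    n_storms = int(storm_days(window.reset_index(), threshold_mm).sum())
    day0 = idx.loc[start]
    return {
        "nest_id": nest.nest_id,
        "W_avg": total_rain / n_days,
        "S_avg": n_storms / n_days,
        "R": "yes" if day0["weather_c"] == "rain" else "no",
        "T": float(day0["tmin_c"]),
        "D": float(day0["tmax_c"] - day0["tmin_c"]),
    }


def nest_climate_table(records, ages: pd.DataFrame, climate: pd.DataFrame,
                       threshold_mm: float = 20.0) -> pd.DataFrame:
    """Per-nest climate covariates for a whole cohort."""
    age_by_id = {r.nest_id: NestAge(r.nest_id, int(r.age_days), bool(r.censored))
                 for r in ages.itertuples()}
    idx = climate.set_index("date")
    rows = []
    for nest in records:
        if nest.nest_id not in age_by_id:
            raise ValidationError(f"no age for nest {nest.nest_id}")
        rows.append(nest_climate(nest, age_by_id[nest.nest_id],
                                 idx.reset_index(), threshold_mm))
    return pd.DataFrame(rows)


def aggregate_climate(climate: pd.DataFrame, by: str = "month",
                      threshold_mm: float = 20.0) -> pd.DataFrame:
    """Totals per calendar period: rain, storm count, mean diurnal
    temperature range.  ``by`` is ``"month"`` (YYYY-MM) or ``"year"``."""
    if by not in ("month", "year"):
        raise ValueError("by must be 'month' or 'year'")
    if climate.empty:
        return pd.DataFrame(columns=["period", "total_rain_mm", "n_storms",
                                     "mean_diff_temp_c"])
    df = climate.copy()
    dates = pd.to_datetime(df["date"])
    df["period"] = dates.dt.strftime("%Y-%m") if by == "month" else \
        dates.dt.year.astype(str)
    df["total"] = df["rain_day_mm"] + df["rain_night_mm"]
    df["storm"] = storm_days(df, threshold_mm)
    df["dtr"] = df["tmax_c"] - df["tmin_c"]
    out = df.groupby("period", sort=True).agg(
        total_rain_mm=("total", "sum"),
        n_storms=("storm", "sum"),
        mean_diff_temp_c=("dtr", "mean"),
    ).reset_index()
    return out
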