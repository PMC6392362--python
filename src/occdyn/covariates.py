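"""Climate and habitat covariate engineering.

Builds the route-by-year covariate table consumed by the occupancy
models from two tabular inputs: daily minimum/maximum temperatures per
route, and habitat fractions per route for the three land-cover survey
years. The climate indices are degree-hour style exposure counts —
annual hours above a heat-stress threshold and below a cold-stress
threshold, accumulated over a June 1 – May 31 breeding cycle and
smoothed with a trailing multi-year moving average. All covariates are
z-scored over the full route-by-year stack and then split into a
route-mean (spatial) component and a within-route temporal deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiurnalTiming",
    "interpolate_hourly",
    "hourly_series",
    "stress_hours",
    "moving_average",
    "assign_landcover_years",
    "standardize",
    "Standardizer",
    "decompose",
    "build_covariate_table",
    "HOT_THRESHOLD_C",
    "COLD_THRESHOLD_C",
]

HOT_THRESHOLD_C = 38.0
COLD_THRESHOLD_C = 18.0

#: Land-cover survey year applied to each modeled year.
LANDCOVER_YEAR_MAP = {y: 2001 for y in range(1997, 2002)}
LANDCOVER_YEAR_MAP.update({y: 2006 for y in range(2002, 2007)})
LANDCOVER_YEAR_MAP.update({y: 2011 for y in range(2007, 2013)})

# Fraction of the day's diurnal range retained at sunset before the
# overnight square-root decay toward the next morning's minimum.
_SUNSET_RANGE_FACTOR = 0.39


@dataclass(frozen=True)
class DiurnalTiming:
    """Hours (0-24 clock) anchoring the piecewise diurnal curve."""

    sunrise: float = 6.0
    peak: float = 15.0
    sunset: float = 20.0

    def __post_init__(self) -> None:
        if not self.sunrise < self.peak:
            raise ValueError("timing must satisfy sunrise < peak")
        if not self.peak <= self.sunset < 24.0:
            raise ValueError("timing must satisfy peak <= sunset < 24")


def _diurnal_curve(
    hours: np.ndarray,
    tmin_today: float,
    tmax_today: float,
    tmin_tomorrow: float,
    timing: DiurnalTiming,
) -> np.ndarray:
    """Piecewise sine-daytime / square-root-night temperature curve.

    Rises from the daily minimum at sunrise to the maximum at the peak
    hour along a quarter sine wave, eases back to a sunset temperature
    along a second sine segment, then decays overnight toward the next
    day's minimum proportionally to the square root of time since
    sunset. Pre-sunrise hours use the tail of an identical previous-day
    night segment so that a constant day yields a constant curve.
    """
    hr, pk, st = timing.sunrise, timing.peak, timing.sunset
    rng = tmax_today - tmin_today
    t_sunset = tmax_today - _SUNSET_RANGE_FACTOR * rng
    night_len = hr + 24.0 - st
    out = np.empty_like(hours, dtype=float)

    rise = (hours >= hr) & (hours <= pk)
    out[rise] = tmin_today + rng * np.sin(
        0.5 * np.pi * (hours[rise] - hr) / (pk - hr)
    )
    fall = (hours > pk) & (hours <= st)
    if st > pk:
        out[fall] = t_sunset + (tmax_today - t_sunset) * np.cos(
            0.5 * np.pi * (hours[fall] - pk) / (st - pk)
        )
    night = hours > st
    b = (tmin_tomorrow - t_sunset) / np.sqrt(night_len)
    out[night] = t_sunset + b * np.sqrt(hours[night] - st)
    # pre-sunrise: previous night's decay, assuming yesterday looked like today
    pre = hours < hr
    out[pre] = t_sunset + (tmin_today - t_sunset) / np.sqrt(night_len) * np.sqrt(
        hours[pre] + 24.0 - st
    )
    return out


def interpolate_hourly(
    tmin_today: float,
    tmax_today: float,
    tmin_tomorrow: float,
    timing: DiurnalTiming | None = None,
) -> np.ndarray:
    """24 on-the-hour temperatures for one day (hours 0..23).

    The curve attains ``tmin_today`` at sunrise and ``tmax_today`` at
    the peak hour and decays overnight toward ``tmin_tomorrow``.
    """
    timing = timing or DiurnalTiming()
    if tmin_today > tmax_today:
        raise ValueError(
            f"tmin {tmin_today} exceeds tmax {tmax_today}; inverted inputs"
        )
    hours = np.arange(24.0)
    return _diurnal_curve(hours, tmin_today, tmax_today, tmin_tomorrow, timing)


def hourly_series(daily: pd.DataFrame, timing: DiurnalTiming | None = None) -> pd.Series:
    """Hour-indexed temperature series from a contiguous daily table.

    ``daily`` must have columns ``date`` (datetime-like, contiguous
    days), ``tmin_c`` and ``tmax_c``. The last day borrows its own
    minimum as the following morning's target.
    """
    timing = timing or DiurnalTiming()
    dates = pd.to_datetime(daily["date"]).reset_index(drop=True)
    if len(dates) == 0:
        raise ValueError("empty daily temperature table")
    gaps = dates.diff().dropna()
    if not (gaps == pd.Timedelta(days=1)).all():
        raise ValueError("daily temperature dates must be contiguous")
    tmin = daily["tmin_c"].to_numpy(dtype=float)
    tmax = daily["tmax_c"].to_numpy(dtype=float)
    if np.any(tmin > tmax):
        bad = int(np.argmax(tmin > tmax))
        raise ValueError(f"tmin > tmax on {dates.iloc[bad].date()}")
    tmin_next = np.roll(tmin, -1)
    tmin_next[-1] = tmin[-1]
    values = np.concatenate(
        [
            interpolate_hourly(tmin[i], tmax[i], tmin_next[i], timing)
            for i in range(len(dates))
        ]
    )
    index = pd.date_range(dates.iloc[0], periods=len(values), freq="h")
    return pd.Series(values, index=index, name="temp_c")


def _cycle_year(index: pd.DatetimeIndex) -> np.ndarray:
    """Label each hour by the calendar year in which its Jun 1–May 31 cycle ends."""
    return np.where(index.month >= 6, index.year + 1, index.year)


def stress_hours(
    hourly: pd.Series,
    hot_threshold: float = HOT_THRESHOLD_C,
    cold_threshold: float = COLD_THRESHOLD_C,
) -> pd.DataFrame:
    """Annual heat/cold exposure per breeding cycle (June 1 – May 31).

    Counts hours strictly above ``hot_threshold`` and strictly below
    ``cold_threshold`` within each complete cycle, labeled by the
    calendar year in which the cycle ends. Incomplete cycles raise.
    """
    if not isinstance(hourly.index, pd.DatetimeIndex):
        raise TypeError("hourly series must be indexed by timestamps")
    cyc = _cycle_year(hourly.index)
    frames = []
    for year in np.unique(cyc):
        sel = hourly[cyc == year]
        expected = 8784 if _cycle_has_leap_day(int(year)) else 8760
        if len(sel) != expected:
            raise ValueError(
                f"cycle ending {year} covers {len(sel)} hours, expected {expected} "
                f"(gap between {sel.index.min()} and {sel.index.max()})"
            )
        frames.append(
            {
                "year": int(year),
                "heat_hours": int((sel > hot_threshold).sum()),
                "cold_hours": int((sel < cold_threshold).sum()),
            }
        )
    return pd.DataFrame(frames).set_index("year")


def _cycle_has_leap_day(end_year: int) -> bool:
    y = end_year  # Feb 29 of the end year falls inside the Jun–May cycle
    return y % 4 == 0 and (y % 100 != 0 or y % 400 == 0)


def moving_average(series: pd.Series, window: int = 15) -> pd.Series:
    """Trailing mean over ``window`` entries, labeled by the ending index."""
    if len(series) < window:
        raise ValueError(
            f"series of length {len(series)} shorter than window {window}"
        )
    return series.rolling(window).mean().dropna()


def assign_landcover_years(
    frac_2001: float,
    frac_2006: float,
    frac_2011: float,
    years=range(1997, 2013),
) -> pd.Series:
    """Step series of habitat fractions over the modeled years.

    2001 values stand in for 1997–2001, 2006 values for 2002–2006 and
    2011 values for 2007–2012.
    """
    by_survey = {2001: frac_2001, 2006: frac_2006, 2011: frac_2011}
    for y, v in by_survey.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"habitat fraction for {y} out of [0, 1]: {v}")
    vals = {}
    for y in years:
        if y not in LANDCOVER_YEAR_MAP:
            raise ValueError(f"no land-cover mapping defined for year {y}")
        vals[y] = by_survey[LANDCOVER_YEAR_MAP[y]]
    return pd.Series(vals, name="habitat_frac")


@dataclass(frozen=True)
class Standardizer:
    """Stored z-transform parameters, reusable on new data."""

    mean: float
    sd: float

    def apply(self, values):
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def invert(self, values):
        return np.asarray(values, dtype=float) * self.sd + self.mean


def standardize(values, scaler: Standardizer | None = None):
    """Z-score ``values``; returns ``(standardized, Standardizer)``.

    Uses the population standard deviation. Passing a stored
    ``Standardizer`` re-applies a previous transform instead of
    refitting (so engineered training-set scaling can be reused).
    """
    arr = np.asarray(values, dtype=float)
    if scaler is None:
        sd = float(arr.std())
        if sd == 0.0:
            raise ValueError("cannot standardize a zero-variance covariate")
        scaler = Standardizer(mean=float(arr.mean()), sd=sd)
    return scaler.apply(arr), scaler


def decompose(table: pd.DataFrame, column: str) -> pd.DataFrame:
    """Split a route-by-year column into route means and deviations.

    Expects ``route_id`` and ``year`` columns. Returns a copy with
    ``{column}_mean`` (constant within route) and ``{column}_dev``
    (zero-mean within route) added; their sum reconstructs the input
    exactly.
    """
    out = table.copy()
    grp = out.groupby("route_id")[column]
    out[f"{column}_mean"] = grp.transform("mean")
    out[f"{column}_dev"] = out[column] - out[f"{column}_mean"]
    return out


def build_covariate_table(
    landcover: pd.DataFrame,
    daily_temps: pd.DataFrame | None = None,
    stress: pd.DataFrame | None = None,
    years=range(1997, 2013),
    window: int = 15,
    timing: DiurnalTiming | None = None,
) -> pd.DataFrame:
    """Assemble the standardized route-by-year covariate table.

    ``landcover`` has columns ``route_id, frac_2001, frac_2006,
    frac_2011``. Climate enters either as ``daily_temps`` (columns
    ``route_id, date, tmin_c, tmax_c``; run through hourly
    interpolation, stress-hour accumulation and the trailing moving
    average) or as a precomputed ``stress`` table (``route_id, year,
    heat_hours, cold_hours``) already on the modeled-year grid.

    Returns columns: raw ``habitat_frac, heat_hours, cold_hours`` plus
    ``*_mean`` / ``*_dev`` standardized components per covariate.
    """
    years = list(years)
    rows = []
    for _, rec in landcover.iterrows():
        series = assign_landcover_years(
            rec["frac_2001"], rec["frac_2006"], rec["frac_2011"], years
        )
        for y, v in series.items():
            rows.append({"route_id": rec["route_id"], "year": int(y), "habitat_frac": v})
    table = pd.DataFrame(rows)

    if (daily_temps is None) == (stress is None):
        raise ValueError("provide exactly one of daily_temps or stress")
    if daily_temps is not None:
        frames = []
        for route_id, sub in daily_temps.groupby("route_id"):
            hourly = hourly_series(sub.sort_values("date"), timing)
            annual = stress_hours(hourly)
            smooth = pd.DataFrame(
                {
                    "heat_hours": moving_average(annual["heat_hours"], window),
                    "cold_hours": moving_average(annual["cold_hours"], window),
                }
            )
            smooth["route_id"] = route_id
            smooth["year"] = smooth.index
            frames.append(smooth.reset_index(drop=True))
        stress = pd.concat(frames, ignore_index=True)
    stress = stress[["route_id", "year", "heat_hours", "cold_hours"]]

    table = table.merge(stress, on=["route_id", "year"], how="left")
    missing = table[table[["heat_hours", "cold_hours"]].isna().any(axis=1)]
    if not missing.empty:
        first = missing.iloc[0]
        raise ValueError(
            f"no climate values for route {first['route_id']}, year {first['year']}"
        )

    for raw, name in (
        ("habitat_frac", "habitat"),
        ("heat_hours", "heat"),
        ("cold_hours", "cold"),
    ):
        z, _ = standardize(table[raw].to_numpy())
        table[f"{name}_z"] = z
        table = decompose(table, f"{name}_z")
        table = table.rename(
            columns={f"{name}_z_mean": f"{name}_mean", f"{name}_z_dev": f"{name}_dev"}
        )
    return table
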