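"""Daily reductions of 30-min traces: radius statistics and climate
aggregates.

Days run midnight-to-midnight in local standard time (sensors log at fixed
cadence; no daylight-saving shifts).  A day's radius metrics are reported
only when at least ``min_coverage`` of its 48 half-hour records are
present; otherwise the day stays in the table with null metrics so that
gaps remain visible downstream.  The growing season is April 1 through
September 30.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import ensure_vpd
from .traces import ClimateTrace, SensorTrace, RECORDS_PER_DAY

GROWING_SEASON_MONTHS = (4, 5, 6, 7, 8, 9)

METRIC_COLUMNS = [
    "daily_mean", "daily_max", "daily_min", "amplitude",
    "time_of_max", "time_of_min", "daily_mean_change",
]


def growing_season_mask(dates: pd.DatetimeIndex) -> np.ndarray:
    """Boolean mask selecting April–September dates."""
    return np.asarray(np.isin(dates.month, GROWING_SEASON_MONTHS))


def _clock_hour(ts: pd.Timestamp) -> float:
    return ts.hour + ts.minute / 60.0


def daily_radius_stats(trace: SensorTrace, min_coverage: float = 0.9) -> pd.DataFrame:
    """Per-day radius statistics for one trace.

    Returns a DataFrame indexed by calendar date with ``daily_mean``,
    ``daily_max``, ``daily_min``, ``amplitude`` (max − min), ``time_of_max``
    and ``time_of_min`` (clock hours; ties broken by earliest occurrence),
    ``daily_mean_change`` (this day's mean minus the previous calendar
    day's mean, the "daily mean approach"), and ``n_records``.  Days with
    fewer than ``min_coverage``·48 valid records keep their row but carry
    null metrics.
    """
    radius = trace.radius
    days = radius.index.normalize()
    full_days = pd.date_range(days.min(), days.max(), freq="D")
    rows = {}
    grouped = radius.groupby(days)
    for day in full_days:
        if day in grouped.groups:
            vals = grouped.get_group(day).dropna()
        else:
            vals = pd.Series(dtype=float)
        n = len(vals)
        if n < min_coverage * RECORDS_PER_DAY:
            rows[day] = dict.fromkeys(METRIC_COLUMNS, np.nan) | {"n_records": n}
            continue
        vmax, vmin = vals.max(), vals.min()
        rows[day] = {
            "daily_mean": vals.mean(),
            "daily_max": vmax,
            "daily_min": vmin,
            "amplitude": vmax - vmin,
            "time_of_max": _clock_hour(vals.index[vals.to_numpy() == vmax][0]),
            "time_of_min": _clock_hour(vals.index[vals.to_numpy() == vmin][0]),
            "daily_mean_change": np.nan,
            "n_records": n,
        }
    out = pd.DataFrame.from_dict(rows, orient="index").reindex(full_days)
    out.index.name = "date"
    out["daily_mean_change"] = out["daily_mean"] - out["daily_mean"].shift(1)
    out.insert(0, "tree_id", trace.tree_id)
    out.insert(1, "position", trace.position)
    return out


def daily_mean_change(trace: SensorTrace, min_coverage: float = 0.9) -> pd.Series:
    """Day-to-day change of the daily mean radius (µm), assigned to the
    later day; null when either day is null."""
    stats = daily_radius_stats(trace, min_coverage)
    if stats["daily_mean"].notna().sum() < 2:
        raise ValidationError("daily_mean_change needs at least 2 valid days")
    return stats["daily_mean_change"].rename("daily_mean_change_um")


def daily_climate(climate: ClimateTrace) -> pd.DataFrame:
    """Daily climate aggregates: max/mean/min for T, VPD and RH, means for
    SR and SWC, and the precipitation daily total."""
    climate = ensure_vpd(climate)
    df = climate.data
    days = df.index.normalize()
    agg = df.groupby(days).agg(
        t_max=("t_air_c", "max"),
        t_mean=("t_air_c", "mean"),
        t_min=("t_air_c", "min"),
        vpd_max=("vpd_kpa", "max"),
        vpd_mean=("vpd_kpa", "mean"),
        vpd_min=("vpd_kpa", "min"),
        rh_max=("rh_pct", "max"),
        rh_mean=("rh_pct", "mean"),
        rh_min=("rh_pct", "min"),
        sr_mean=("sr_wm2", "mean"),
        swc_mean=("swc_volpct", "mean"),
        p_sum=("p_mm", "sum"),
    )
    agg.index.name = "date"
    return agg


def growing_season_summary(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-year April–September climate summary (seasonal mean with the
    seasonal maximum in a companion column).

    ``p_sum`` is the seasonal precipitation total with the largest daily
    total as its maximum; the other variables are means of daily means with
    maxima of daily maxima (daily means for SWC).
    """
    mask = growing_season_mask(daily.index)
    season = daily[mask]
    if season.empty:
        raise ValidationError("no April–September days in the daily climate table")
    rows = []
    for year, grp in season.groupby(season.index.year):
        rows.append(
            {
                "year": year,
                "t_mean": grp["t_mean"].mean(),
                "t_max": grp["t_max"].max(),
                "vpd_mean": grp["vpd_mean"].mean(),
                "vpd_max": grp["vpd_max"].max(),
                "p_total": grp["p_sum"].sum(),
                "p_daily_max": grp["p_sum"].max(),
                "swc_mean": grp["swc_mean"].mean(),
                "swc_max": grp["swc_mean"].max(),
            }
        )
    return pd.DataFrame(rows).set_index("year")
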