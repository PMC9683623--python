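"""Annual exposure indices from hourly derived thermal measures.

Aggregates the hourly temperature / heat-index / WBGT series into the
catalogue of 30 annual indices used by the rate models: absolute degree
statistics (mean of daily means, mean of daily maxima), hour counts above
fixed thresholds, and relative statistics (mean daily anomaly, days more
than one standard deviation above the day-of-year climatology), each over
the full calendar year or the heat season (May 1 - September 30).

Day boundaries follow the local standard time of the timestamps; the
climatological baseline defaults to 1990-2019 with Feb 29 keyed separately
from leap years only. Threshold statistics use strict ">" comparisons, so
ties at a threshold never count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DataIntegrityError, InvalidInputError

__all__ = [
    "INDEX_TYPES",
    "IndexSpec",
    "index_catalogue",
    "daily_summaries",
    "build_climatology",
    "compute_annual_index",
    "compute_all_indices",
    "HEAT_SEASON",
]

INDEX_TYPES = ("temperature", "heat_index", "wbgt")

#: hourly column (°F) backing each index type
HOURLY_COLUMN = {
    "temperature": "t_air_f",
    "heat_index": "hi_f",
    "wbgt": "wbgt_f",
}

#: heat season window, (month, day) inclusive bounds
HEAT_SEASON = ((5, 1), (9, 30))

#: hour-count thresholds (°F) per index type
HOURS_ABOVE_THRESHOLDS = {
    "temperature": (90.0, 100.0),
    "heat_index": (90.0, 105.0),
    "wbgt": (85.0, 90.0),
}

STATISTICS = (
    "mean_of_daily_mean",
    "mean_of_daily_max",
    "hours_above",
    "mean_anomaly",
    "days_above_1sd",
)


@dataclass(frozen=True)
class IndexSpec:
    """One annual exposure index definition.

    ``threshold`` (°F) is required exactly when ``statistic`` is
    'hours_above'. ``window`` is 'full_year' or 'heat_season'.
    """

    index_type: str
    statistic: str
    threshold: float | None = None
    window: str = "full_year"

    def __post_init__(self):
        if self.index_type not in INDEX_TYPES:
            raise InvalidInputError(f"unknown index_type '{self.index_type}'")
        if self.statistic not in STATISTICS:
            raise InvalidInputError(f"unknown statistic '{self.statistic}'")
        if self.window not in ("full_year", "heat_season"):
            raise InvalidInputError(f"unknown window '{self.window}'")
        if (self.threshold is not None) != (self.statistic == "hours_above"):
            raise InvalidInputError(
                "threshold must be given exactly when statistic='hours_above'"
            )

    @property
    def units(self) -> str:
        return {"hours_above": "hours", "days_above_1sd": "days"}.get(
            self.statistic, "degF"
        )

    @property
    def label(self) -> str:
        core = {
            "mean_of_daily_mean": "mean",
            "mean_of_daily_max": "max",
            "mean_anomaly": "anomaly",
            "days_above_1sd": "days_gt_1sd",
        }.get(self.statistic, f"hours_gt_{self.threshold:g}")
        suffix = "_hs" if self.window == "heat_season" else ""
        return f"{self.index_type}_{core}{suffix}"


def index_catalogue() -> list[IndexSpec]:
    """The full 30-index catalogue.

    Per index type (temperature, heat index, WBGT): mean-of-daily-mean and
    mean-of-daily-max for both windows (12), two hour-count thresholds for
    the full year (6), and mean-anomaly plus days-above-1-SD for both
    windows (12).
    """
    specs: list[IndexSpec] = []
    for itype in INDEX_TYPES:
        for window in ("full_year", "heat_season"):
            specs.append(IndexSpec(itype, "mean_of_daily_mean", window=window))
            specs.append(IndexSpec(itype, "mean_of_daily_max", window=window))
        for thr in HOURS_ABOVE_THRESHOLDS[itype]:
            specs.append(IndexSpec(itype, "hours_above", threshold=thr))
        for window in ("full_year", "heat_season"):
            specs.append(IndexSpec(itype, "mean_anomaly", window=window))
            specs.append(IndexSpec(itype, "days_above_1sd", window=window))
    return specs


def _require_columns(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} missing column(s): {missing}")


def daily_summaries(derived: pd.DataFrame,
                    completeness: float = 0.9) -> pd.DataFrame:
    """Daily mean/max of each hourly index, per location and calendar date.

    Returns a long table (location_id, date, index_type, daily_mean,
    daily_max, n_hours, complete). Days with fewer than
    ``ceil(completeness * 24)`` hours are flagged ``complete=False``; they
    still carry their statistics so hour-count aggregations can use every
    available hour.
    """
    _require_columns(derived, ["location_id", "timestamp"], "derived hourly table")
    present = [t for t in INDEX_TYPES if HOURLY_COLUMN[t] in derived.columns]
    if not present:
        raise InvalidInputError(
            "derived hourly table has none of the index columns "
            f"{list(HOURLY_COLUMN.values())}"
        )
    if derived.duplicated(subset=["location_id", "timestamp"]).any():
        raise DataIntegrityError("duplicate (location_id, timestamp) rows")
    if len(derived) == 0:
        return pd.DataFrame(
            columns=["location_id", "date", "index_type", "daily_mean",
                     "daily_max", "n_hours", "complete"]
        )
    min_hours = int(np.ceil(completeness * 24))
    ts = pd.DatetimeIndex(derived["timestamp"])
    frames = []
    for itype in present:
        col = HOURLY_COLUMN[itype]
        g = (
            pd.DataFrame({
                "location_id": derived["location_id"].to_numpy(),
                "date": ts.normalize(),
                "value": derived[col].to_numpy(dtype=float),
            })
            .groupby(["location_id", "date"], sort=True)["value"]
            .agg(daily_mean="mean", daily_max="max", n_hours="count")
            .reset_index()
        )
        g.insert(2, "index_type", itype)
        frames.append(g)
    out = pd.concat(frames, ignore_index=True)
    out["complete"] = out["n_hours"] >= min_hours
    return out


def build_climatology(daily: pd.DataFrame,
                      baseline_years: tuple[int, int] = (1990, 2019)
                      ) -> pd.DataFrame:
    """Day-of-year baseline mean and SD of the daily mean, per location.

    Statistics are taken across the baseline years (default 1990-2019) for
    each (location, index_type, month, day); Feb 29 uses leap years only.
    Incomplete days are excluded. Raises if any calendar day has fewer than
    two baseline years (sample SD undefined).
    """
    _require_columns(
        daily, ["location_id", "date", "index_type", "daily_mean"], "daily table"
    )
    d = daily[daily.get("complete", True)].copy()
    dates = pd.DatetimeIndex(d["date"])
    y0, y1 = baseline_years
    in_base = (dates.year >= y0) & (dates.year <= y1)
    d = d[in_base]
    if len(d) == 0:
        raise InvalidInputError(
            f"no daily data within baseline years {y0}-{y1}"
        )
    dates = pd.DatetimeIndex(d["date"])
    d["month"] = dates.month
    d["day"] = dates.day
    clim = (
        d.groupby(["location_id", "index_type", "month", "day"], sort=True)[
            "daily_mean"
        ]
        .agg(clim_mean="mean", clim_sd=lambda s: s.std(ddof=1), n_years="count")
        .reset_index()
    )
    thin = clim[clim["n_years"] < 2]
    if len(thin):
        r = thin.iloc[0]
        raise InvalidInputError(
            "fewer than 2 baseline years for calendar day "
            f"{int(r['month']):02d}-{int(r['day']):02d} at {r['location_id']} "
            "(sample SD undefined)"
        )
    return clim


def _window_mask_dates(dates: pd.DatetimeIndex, window: str) -> np.ndarray:
    if window == "full_year":
        return np.ones(len(dates), dtype=bool)
    (m0, d0), (m1, d1) = HEAT_SEASON
    md = dates.month * 100 + dates.day
    return (md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)


def compute_annual_index(daily: pd.DataFrame, hourly: pd.DataFrame,
                         clim: pd.DataFrame | None, spec: IndexSpec,
                         year: int) -> pd.DataFrame:
    """Evaluate one IndexSpec for every location in one year.

    ``daily`` is the output of :func:`daily_summaries`, ``hourly`` the
    derived hourly table (needed only for 'hours_above'), and ``clim`` the
    climatology (needed only for relative statistics). Mean statistics use
    complete days only; hour counts use all available hours. Returns a tidy
    frame (location_id, year, index_type, statistic, threshold, window,
    value).
    """
    if spec.statistic == "hours_above":
        col = HOURLY_COLUMN[spec.index_type]
        _require_columns(hourly, ["location_id", "timestamp", col], "hourly table")
        ts = pd.DatetimeIndex(hourly["timestamp"])
        m = (ts.year == year) & _window_mask_dates(ts, spec.window)
        sub = hourly[m]
        vals = sub[col].to_numpy(dtype=float)
        counts = (
            pd.Series(vals > spec.threshold, index=sub["location_id"].to_numpy())
            .groupby(level=0)
            .sum()
            .astype(int)
        )
        out = counts.rename("value").rename_axis("location_id").reset_index()
    else:
        d = daily[daily["index_type"] == spec.index_type].copy()
        dates = pd.DatetimeIndex(d["date"])
        m = (dates.year == year) & _window_mask_dates(dates, spec.window)
        d = d[m & d.get("complete", True)]
        if spec.statistic in ("mean_anomaly", "days_above_1sd"):
            if clim is None:
                raise InvalidInputError(
                    f"climatology required for statistic '{spec.statistic}'"
                )
            dd = pd.DatetimeIndex(d["date"])
            d = d.assign(month=dd.month, day=dd.day)
            merged = d.merge(
                clim[clim["index_type"] == spec.index_type],
                on=["location_id", "index_type", "month", "day"],
                how="left",
            )
            if merged["clim_mean"].isna().any():
                bad = merged[merged["clim_mean"].isna()].iloc[0]
                raise InvalidInputError(
                    "missing climatology for calendar day "
                    f"{int(bad['month']):02d}-{int(bad['day']):02d} at "
                    f"{bad['location_id']}"
                )
            if spec.statistic == "mean_anomaly":
                merged["stat"] = merged["daily_mean"] - merged["clim_mean"]
                out = (
                    merged.groupby("location_id")["stat"].mean().rename("value")
                    .reset_index()
                )
            else:
                merged["stat"] = (
                    merged["daily_mean"] > merged["clim_mean"] + merged["clim_sd"]
                )
                out = (
                    merged.groupby("location_id")["stat"].sum().astype(int)
                    .rename("value").reset_index()
                )
        elif spec.statistic == "mean_of_daily_mean":
            out = (
                d.groupby("location_id")["daily_mean"].mean().rename("value")
                .reset_index()
            )
        else:  # mean_of_daily_max
            out = (
                d.groupby("location_id")["daily_max"].mean().rename("value")
                .reset_index()
            )
    out["year"] = year
    out["index_type"] = spec.index_type
    out["statistic"] = spec.statistic
    out["threshold"] = np.nan if spec.threshold is None else spec.threshold
    out["window"] = spec.window
    return out[
        ["location_id", "year", "index_type", "statistic", "threshold",
         "window", "value"]
    ]


def compute_all_indices(derived: pd.DataFrame,
                        clim: pd.DataFrame | None = None,
                        years=None,
                        completeness: float = 0.9,
                        specs: list[IndexSpec] | None = None) -> pd.DataFrame:
    """Evaluate the full index catalogue for every location-year.

    ``derived`` is the hourly table from ``met.derive_hourly``. If ``clim``
    is None it is built from ``derived`` itself over the default baseline.
    ``years`` defaults to every year present. Returns one row per
    (location, year, spec): 30 rows per location-year for the default
    catalogue.
    """
    if len(derived) == 0:
        return pd.DataFrame(
            columns=["location_id", "year", "index_type", "statistic",
                     "threshold", "window", "value"]
        )
    daily = daily_summaries(derived, completeness=completeness)
    if clim is None:
        clim = build_climatology(daily)
    if years is None:
        years = sorted(pd.DatetimeIndex(derived["timestamp"]).year.unique())
    specs = index_catalogue() if specs is None else specs
    frames = [
        compute_annual_index(daily, derived, clim, spec, int(year))
        for year in years
        for spec in specs
    ]
    return pd.concat(frames, ignore_index=True)
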