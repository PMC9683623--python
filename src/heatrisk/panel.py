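"""Installation-year health outcome panel: rates, burden, linear trends.

The panel holds one row per (installation, year, outcome type) with the
heat stress illness (HSI) encounter count, the all-cause encounter count,
and the active-duty population. Rates are expressed per 1,000 persons per
year; burden is the share of all encounters attributable to HSI.

Outcome types carry different valid year spans (reporting before those
spans is known-incomplete and excluded upstream): ambulatory 1998-2018,
hospitalization 1991-2018, reportable events 1995-2018.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataIntegrityError, InvalidInputError

__all__ = [
    "OUTCOME_SPANS",
    "TrendResult",
    "rate",
    "combined_rate",
    "burden",
    "linear_trend",
    "validate_panel",
    "outcome_trends",
    "exposure_trends",
]

OUTCOME_SPANS = {
    "ambulatory": (1998, 2018),
    "hospitalization": (1991, 2018),
    "reportable": (1995, 2018),
}

PANEL_COLUMNS = ["location_id", "year", "outcome_type", "hsi_count",
                 "all_count", "population"]


@dataclass(frozen=True)
class TrendResult:
    """OLS slope of a series on calendar year with its two-sided p-value."""

    slope: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def rate(hsi_count, population):
    """HSI rate per 1,000 persons per year."""
    h = np.asarray(hsi_count, dtype=float)
    p = np.asarray(population, dtype=float)
    if np.any(p <= 0):
        raise InvalidInputError("population must be > 0", field="population")
    if np.any(h < 0):
        raise InvalidInputError("hsi_count must be >= 0", field="hsi_count")
    out = h / p * 1000.0
    return float(out) if out.ndim == 0 else out


def combined_rate(records: pd.DataFrame) -> float:
    """Pooled rate per 1,000 across locations: sum of counts / sum of pop.

    All rows must share one year and one outcome type (the pooled rate is
    only meaningful within a single stratum).
    """
    if len(records) == 0:
        raise InvalidInputError("combined_rate needs at least one record")
    for key in ("year", "outcome_type"):
        if key in records.columns and records[key].nunique() > 1:
            raise InvalidInputError(
                f"combined_rate requires a single {key}; got "
                f"{sorted(records[key].unique())}"
            )
    return rate(records["hsi_count"].sum(), records["population"].sum())


def burden(hsi_count, all_count):
    """HSI encounters as a percentage of all documented encounters."""
    h = np.asarray(hsi_count, dtype=float)
    a = np.asarray(all_count, dtype=float)
    if np.any(a <= 0):
        raise InvalidInputError(
            "all_count must be > 0 for burden", field="all_count"
        )
    out = h / a * 100.0
    return float(out) if out.ndim == 0 else out


def linear_trend(values, years) -> TrendResult:
    """OLS slope of ``values`` on ``years`` with the t-test p-value.

    The two-sided p-value uses the t distribution on n-2 degrees of
    freedom. Requires n >= 3 and non-constant years.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(years, dtype=float)
    if v.shape != y.shape:
        raise InvalidInputError("values and years must have equal length")
    if len(v) < 3:
        raise InvalidInputError("linear_trend requires at least 3 points")
    if np.ptp(y) == 0:
        raise InvalidInputError("years are constant: singular design")
    res = stats.linregress(y, v)
    return TrendResult(slope=float(res.slope), p_value=float(res.pvalue), n=len(v))


def validate_panel(df: pd.DataFrame, strict_spans: bool = False) -> pd.DataFrame:
    """Validate an outcome panel table, returning it unchanged.

    Raises on structural problems (missing columns, negative counts,
    hsi_count > all_count, non-positive population, duplicated keys,
    unknown outcome types). Years outside an outcome type's valid span
    produce a warning by default (``strict_spans=True`` upgrades this to an
    error): the exclusion of early incomplete-reporting years is enforced
    as validation, not re-derived.
    """
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"panel missing column(s): {missing}")
    unknown = set(df["outcome_type"]) - set(OUTCOME_SPANS)
    if unknown:
        raise InvalidInputError(f"unknown outcome type(s): {sorted(unknown)}")
    if df.duplicated(subset=["location_id", "year", "outcome_type"]).any():
        raise DataIntegrityError("duplicate (location, year, outcome_type) rows")
    if (df["hsi_count"] < 0).any() or (df["all_count"] < 0).any():
        raise InvalidInputError("counts must be non-negative")
    if (df["hsi_count"] > df["all_count"]).any():
        raise DataIntegrityError("hsi_count exceeds all_count in some rows")
    if (df["population"] <= 0).any():
        raise InvalidInputError("population must be positive")
    for otype, (y0, y1) in OUTCOME_SPANS.items():
        sub = df[df["outcome_type"] == otype]
        off = sub[(sub["year"] < y0) | (sub["year"] > y1)]
        if len(off):
            msg = (
                f"{len(off)} {otype} row(s) outside the valid span "
                f"{y0}-{y1} (e.g. year {int(off['year'].iloc[0])})"
            )
            if strict_spans:
                raise DataIntegrityError(msg)
            warnings.warn(msg, stacklevel=2)
    return df


def outcome_trends(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-installation and combined linear time trends of outcome rates.

    Returns a tidy frame (location_id, outcome_type, slope, p_value, n,
    significant) where location_id 'combined' pools counts and populations
    across installations before computing the rate series.
    """
    rows = []
    for (loc, otype), g in panel.groupby(["location_id", "outcome_type"]):
        if len(g) < 3:
            continue
        t = linear_trend(rate(g["hsi_count"], g["population"]), g["year"])
        rows.append((loc, otype, t.slope, t.p_value, t.n, t.significant))
    for otype, g in panel.groupby("outcome_type"):
        pooled = (
            g.groupby("year")[["hsi_count", "population"]].sum().reset_index()
        )
        if len(pooled) < 3:
            continue
        t = linear_trend(
            rate(pooled["hsi_count"], pooled["population"]), pooled["year"]
        )
        rows.append(("combined", otype, t.slope, t.p_value, t.n, t.significant))
    return pd.DataFrame(
        rows,
        columns=["location_id", "outcome_type", "slope", "p_value", "n",
                 "significant"],
    )


def exposure_trends(annual: pd.DataFrame) -> pd.DataFrame:
    """Per-installation linear time trend of each annual exposure index."""
    rows = []
    keys = ["location_id", "index_type", "statistic", "threshold", "window"]
    for key, g in annual.groupby(keys, dropna=False):
        if len(g) < 3:
            continue
        t = linear_trend(g["value"], g["year"])
        rows.append((*key, t.slope, t.p_value, t.n, t.significant))
    return pd.DataFrame(
        rows, columns=keys + ["slope", "p_value", "n", "significant"]
    )
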