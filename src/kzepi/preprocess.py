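"""Turn raw inputs into analysis-ready monthly series.

The canonical outcome-side order is: aggregate case events to monthly counts,
take natural logs (stabilises the variance of growing counts and puts
differences on a percentage scale), fit and remove a linear trend by ordinary
least squares, and only then low-pass filter.  Each step is callable on its
own; :mod:`kzepi.pipeline` enforces the order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyInputError,
    GapError,
    InsufficientDataError,
    NonPositiveValueError,
    NoOverlapError,
)
from .series import MonthlyTimeSeries, month_period

__all__ = [
    "TrendFit",
    "aggregate_monthly",
    "log_transform",
    "fit_trend",
    "detrend",
    "annualize_growth",
    "growth_to_monthly_slope",
    "align_common_span",
]

MIN_OVERLAP_WARN = 24  # months below which cross-series analysis is dubious


@dataclass(frozen=True)
class TrendFit:
    """Ordinary-least-squares linear trend on the working scale.

    ``slope`` is the change per month, ``intercept`` the fitted value at the
    anchor month, ``scale`` tags whether the fit was made on natural or log
    values, and ``slope_stderr`` is the classical OLS standard error (useful
    for parameter-recovery checks, not inference on filtered data).
    """

    slope: float
    intercept: float
    scale: str  # {"natural", "log"}
    anchor: pd.Period
    slope_stderr: float = float("nan")

    def predict(self, series: MonthlyTimeSeries) -> np.ndarray:
        """Trend line evaluated at the calendar months of ``series``."""
        offset = (series.start - self.anchor).n
        i = np.arange(len(series)) + offset
        return self.intercept + self.slope * i


def aggregate_monthly(dates, values=None) -> MonthlyTimeSeries:
    """Collapse dated records into one value per calendar month.

    With ``values`` omitted, records are events and the result is the count
    per month (0 for empty months); with ``values`` given, per-month sums.
    Day-of-month is ignored: any day inside a month belongs to that month.
    """
    dates = list(dates)
    if len(dates) == 0:
        raise EmptyInputError("no records to aggregate")
    periods = pd.PeriodIndex(pd.to_datetime(dates), freq="M")
    full = pd.period_range(periods.min(), periods.max(), freq="M")
    if values is None:
        agg = pd.Series(1.0, index=periods).groupby(level=0).sum()
    else:
        vals = np.asarray(list(values), dtype=float)
        if vals.size != len(dates):
            raise EmptyInputError("dates and values differ in length")
        agg = pd.Series(vals, index=periods).groupby(level=0).sum()
    agg = agg.reindex(full, fill_value=0.0)
    return MonthlyTimeSeries(full[0], agg.to_numpy())


def log_transform(series: MonthlyTimeSeries) -> MonthlyTimeSeries:
    """Elementwise natural log; gaps pass through as gaps.

    Zero or negative values raise, naming the offending month — the caller
    must decide on an offset, nothing is added silently.
    """
    vals = series.values
    bad = np.flatnonzero(np.isfinite(vals) & (vals <= 0))
    if bad.size:
        month = series.start + int(bad[0])
        raise NonPositiveValueError(
            f"cannot log-transform nonpositive value {vals[bad[0]]!r} in {month}"
        )
    with np.errstate(invalid="ignore"):
        return series.with_values(np.log(vals))


def fit_trend(series: MonthlyTimeSeries) -> TrendFit:
    """OLS of value on month index (0-based from the anchor)."""
    if series.has_gaps:
        raise GapError("trend fitting requires a gap-free series")
    if len(series) < 3:
        raise InsufficientDataError("need at least 3 points to fit a trend")
    i = np.arange(len(series), dtype=float)
    res = stats.linregress(i, series.values)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        scale="natural",
        anchor=series.start,
        slope_stderr=float(res.stderr),
    )


def detrend(series: MonthlyTimeSeries, fit: TrendFit) -> MonthlyTimeSeries:
    """Subtract the trend line, evaluated at the series' calendar months.

    The fit's anchor need not coincide with the series anchor: the line is
    evaluated with the correct month offset, so a trend fitted on a longer
    record detrends any sub-span consistently.
    """
    return series.with_values(series.values - fit.predict(series))


def annualize_growth(monthly_log_slope: float) -> float:
    """Percent growth per year implied by a per-month log-scale slope.

    100 * (exp(12 * slope) - 1); e.g. 0.0034/month -> ~4.2 %/yr.
    """
    return 100.0 * np.expm1(12.0 * monthly_log_slope)


def growth_to_monthly_slope(percent_per_year: float) -> float:
    """Inverse of :func:`annualize_growth`."""
    return np.log1p(percent_per_year / 100.0) / 12.0


def align_common_span(
    a: MonthlyTimeSeries, b: MonthlyTimeSeries
) -> tuple[MonthlyTimeSeries, MonthlyTimeSeries]:
    """Crop both series to their common calendar span.

    The window runs from the later of the two starts to the earlier of the
    two ends; the results share anchor and length.  Overlaps shorter than
    two years trigger a warning, disjoint spans an error.
    """
    lo = max(month_period(a.start), month_period(b.start))
    hi = min(a.end, b.end)
    if hi < lo:
        raise NoOverlapError(f"spans {a.start}..{a.end} and {b.start}..{b.end} are disjoint")
    n = (hi - lo).n + 1
    if n < MIN_OVERLAP_WARN:
        warnings.warn(
            f"common span is only {n} months; cross-series results will be fragile",
            stacklevel=2,
        )
    return a.crop(lo, hi), b.crop(lo, hi)
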