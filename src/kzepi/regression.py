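"""Lagged simple linear regression and effect-size conversions.

After a latency is chosen from the cross-correlation profile, the long-term
outcome component is regressed on the lagged predictor by ordinary least
squares.  Because the outcome is a deviation of natural-log counts, the slope
("coefficient of influence", log-cases per sunspot) converts to a percentage
change via 100*(exp(slope * delta) - 1).  R-squared is reported as the
squared Pearson correlation at the chosen lag — with moving-average-filtered
series consecutive points are strongly autocorrelated, so this is a
quality-of-fit measure, not an inferential statistic; no standard errors or
p-values are produced.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidParameterError
from .lagcorr import lagged_pairs
from .series import MonthlyTimeSeries

__all__ = [
    "RegressionFit",
    "fit_lagged_regression",
    "r_squared_from_r",
    "percent_effect",
    "sn_effect_to_tsi",
]


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of outcome on lagged predictor over their pairing."""

    slope: float  # outcome units per predictor unit
    intercept: float
    r: float
    r_squared: float  # exactly r**2
    n: int
    lag_months: int


def fit_lagged_regression(
    x: MonthlyTimeSeries, y: MonthlyTimeSeries, lag: int
) -> RegressionFit:
    """OLS of y on x lagged ``lag`` months, over the same pairs the
    cross-correlation uses (so ``r`` matches it exactly)."""
    xv, yv = lagged_pairs(x, y, lag)
    res = stats.linregress(xv, yv)
    r = float(res.rvalue)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=r,
        r_squared=r * r,
        n=xv.size,
        lag_months=int(lag),
    )


def r_squared_from_r(r: float) -> float:
    """Coefficient of explanation: the squared correlation coefficient."""
    if abs(r) > 1.0:
        raise InvalidParameterError(f"|r| must be <= 1, got {r}")
    return r * r


def percent_effect(log_slope: float, delta_sn: float) -> float:
    """Percent change in the outcome per ``delta_sn`` change in the predictor.

    Valid because the outcome is on a natural-log scale: a log difference of
    ``log_slope * delta_sn`` is a multiplicative factor, so the percentage is
    100 * (exp(log_slope * delta_sn) - 1).  E.g. slope 0.0003 per sunspot
    gives 3.05% per 100 sunspots.  Exactly multiplicative across increments:
    (1 + p(a)/100)(1 + p(b)/100) = 1 + p(a+b)/100.
    """
    return 100.0 * np.expm1(log_slope * delta_sn)


def sn_effect_to_tsi(slope_w_per_sn: float, delta_sn: float) -> float:
    """Irradiance change (W/m^2) for a sunspot-count change, from the linear
    TSI-on-SN slope; e.g. 0.0081 W/m^2 per sunspot -> 0.81 W/m^2 per 100."""
    return slope_w_per_sn * delta_sn
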