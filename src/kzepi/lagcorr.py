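"""Lagged cross-correlation and latency-candidate detection.

The lag convention is one-sided and causal: a positive lag of ``t`` months
means the predictor (solar) series *leads* the outcome — the outcome value in
calendar month ``s`` is paired with the predictor value in month ``s - t``.
For quasi-periodic signals the correlation-versus-lag profile is itself
periodic, so a true latency ``t0`` is echoed at ``t0`` plus integer multiples
of the signal period; candidates are local maxima inside an epidemiologically
plausible window (e.g. 0-70 years, between disease onset and lifespan) and
the working choice among them is the lag that maximises the correlation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyInputError,
    InsufficientOverlapError,
    InvalidParameterError,
)
from .series import MonthlyTimeSeries

__all__ = [
    "LagCorrelationProfile",
    "LatencyCandidate",
    "cross_correlation_at",
    "ccf_profile",
    "find_latency_candidates",
    "best_latency",
]

MIN_PAIRS = 3


def lagged_pairs(
    x: MonthlyTimeSeries, y: MonthlyTimeSeries, lag: int
) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping (x[s - lag], y[s]) pairs over the common calendar months.

    NaN gaps in either member drop the pair.  Raises when fewer than
    MIN_PAIRS pairs remain.  Shared by correlation and regression so the two
    always see identical pairings.
    """
    if lag < 0:
        raise InvalidParameterError("negative lags are out of scope (x must lead y)")
    d = (y.start - x.start).n  # months by which y starts after x
    i0 = max(0, lag - d)
    i1 = min(len(y), len(x) - d + lag)
    if i1 - i0 < MIN_PAIRS:
        raise InsufficientOverlapError(
            f"only {max(0, i1 - i0)} overlapping months at lag {lag}"
        )
    yv = y.values[i0:i1]
    xv = x.values[i0 + d - lag : i1 + d - lag]
    ok = np.isfinite(xv) & np.isfinite(yv)
    if ok.sum() < MIN_PAIRS:
        raise InsufficientOverlapError(
            f"only {int(ok.sum())} gap-free pairs at lag {lag}"
        )
    return xv[ok], yv[ok]


@dataclass(frozen=True)
class LagCorrelationProfile:
    """Correlation r and overlap count n at each integer lag (months)."""

    lags: np.ndarray = field(repr=False)
    r: np.ndarray = field(repr=False)
    n: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=int)
        r = np.asarray(self.r, dtype=float)
        n = np.asarray(self.n, dtype=int)
        if not (lags.shape == r.shape == n.shape) or lags.ndim != 1:
            raise InvalidParameterError("lags, r, n must be 1-d and equal length")
        if (np.diff(lags) <= 0).any():
            raise InvalidParameterError("lags must be strictly increasing")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "n", n)

    def r_at(self, lag: int) -> float:
        idx = np.flatnonzero(self.lags == lag)
        if idx.size == 0:
            raise InvalidParameterError(f"lag {lag} not in profile")
        return float(self.r[idx[0]])


@dataclass(frozen=True)
class LatencyCandidate:
    """A local correlation maximum interpreted as a candidate disease latency."""

    lag_months: int
    lag_years: float  # lag_months / 12, reported to one decimal
    r: float
    n: int
    tied_lags: tuple[int, ...] = ()  # other lags with exactly equal r (from best_latency)


def cross_correlation_at(
    x: MonthlyTimeSeries, y: MonthlyTimeSeries, lag: int
) -> tuple[float, int]:
    """Pearson correlation of y against x lagged ``lag`` months, with the
    overlap count used."""
    xv, yv = lagged_pairs(x, y, lag)
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r, xv.size


def ccf_profile(
    x: MonthlyTimeSeries, y: MonthlyTimeSeries, max_lag: int
) -> LagCorrelationProfile:
    """Profile at every integer lag 0..max_lag with a sufficient overlap.

    Lags whose overlap falls below the minimum are silently omitted; if none
    survives, an insufficient-overlap error is raised.
    """
    if max_lag < 0:
        raise InvalidParameterError("max_lag must be >= 0")
    lags, rs, ns = [], [], []
    for lag in range(max_lag + 1):
        try:
            r, n = cross_correlation_at(x, y, lag)
        except InsufficientOverlapError:
            continue
        lags.append(lag)
        rs.append(r)
        ns.append(n)
    if not lags:
        raise InsufficientOverlapError(
            f"no lag in 0..{max_lag} has {MIN_PAIRS}+ overlapping months"
        )
    return LagCorrelationProfile(np.array(lags), np.array(rs), np.array(ns))


def find_latency_candidates(
    profile: LagCorrelationProfile, min_years: float, max_years: float
) -> list[LatencyCandidate]:
    """Strict local maxima of r within [12*min_years, 12*max_years] months.

    A lag qualifies when its r strictly exceeds both neighbours' in the
    profile; a plateau of equal values counts once, at its lowest lag.
    Results are sorted by lag, with lag_years rounded to one decimal for
    reporting (internal arithmetic stays in integer months).
    """
    if min_years >= max_years:
        raise InvalidParameterError("min_years must be < max_years")
    lo, hi = 12.0 * min_years, 12.0 * max_years
    if hi < profile.lags[0] or lo > profile.lags[-1]:
        raise InvalidParameterError(
            f"window [{min_years}, {max_years}] years is outside the profile range"
        )
    r = profile.r
    out: list[LatencyCandidate] = []
    i = 1
    while i < len(r) - 1:
        if r[i] <= r[i - 1]:
            i += 1
            continue
        j = i  # extend over a plateau of equal values
        while j + 1 < len(r) and r[j + 1] == r[i]:
            j += 1
        if j < len(r) - 1 and r[j + 1] < r[i]:
            lag = int(profile.lags[i])
            if lo <= lag <= hi:
                out.append(
                    LatencyCandidate(
                        lag_months=lag,
                        lag_years=round(lag / 12.0, 1),
                        r=float(r[i]),
                        n=int(profile.n[i]),
                    )
                )
        i = j + 1
    return out


def best_latency(candidates: list[LatencyCandidate]) -> LatencyCandidate:
    """The candidate with maximal r; exact ties resolve to the smallest lag
    and the tied lags are recorded on the winner."""
    if not candidates:
        raise EmptyInputError("no latency candidates to choose from")
    top_r = max(c.r for c in candidates)
    tied = sorted(c.lag_months for c in candidates if c.r == top_r)
    winner = next(c for c in candidates if c.lag_months == tied[0])
    if len(tied) > 1:
        winner = LatencyCandidate(
            winner.lag_months, winner.lag_years, winner.r, winner.n,
            tied_lags=tuple(tied[1:]),
        )
    return winner
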