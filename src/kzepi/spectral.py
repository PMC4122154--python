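"""Periodograms and adaptive smoothing.

Three estimators of spectral content, in increasing order of stability:

* :func:`raw_periodogram` — the classical periodogram at Fourier frequencies.
* :func:`kz_periodogram` (KZP) — the periodogram averaged over all maximally
  overlapping sub-windows of length ``m``, trading frequency resolution for
  estimator variance (a stride-1 Welch-type average with per-window
  demeaning).
* :func:`dz_smooth` — adaptive smoothing in the spirit of DiRienzo-Zurbenko:
  the averaging span at each frequency grows while the power it encloses
  stays below a fraction ``c`` of the total, so spans stay narrow where the
  spectrum is concentrated (peaks survive) and widen where it is flat (noise
  is averaged away).

Frequencies are in cycles per month throughout; period in years = 1/(12 f).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import GapError, InvalidParameterError
from .series import MonthlyTimeSeries

__all__ = [
    "Spectrum",
    "raw_periodogram",
    "kz_periodogram",
    "dz_smooth",
    "dz_half_spans",
    "dominant_frequency",
]


@dataclass(frozen=True)
class Spectrum:
    """Frequency/power pairs plus the parameters that generated them."""

    freqs: np.ndarray = field(repr=False)
    power: np.ndarray = field(repr=False)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise InvalidParameterError("freqs and power must be 1-d, same length")
        if (np.diff(f) <= 0).any():
            raise InvalidParameterError("freqs must be strictly increasing")
        if (p < 0).any():
            raise InvalidParameterError("power must be nonnegative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)

    def __len__(self) -> int:
        return self.freqs.size

    @property
    def period_years(self) -> np.ndarray:
        """1/(12 f); infinite at f = 0."""
        with np.errstate(divide="ignore"):
            return 1.0 / (12.0 * self.freqs)


def _periodogram_rows(rows: np.ndarray) -> np.ndarray:
    """Per-row demeaned periodogram |DFT|^2 / m at frequencies j/m."""
    m = rows.shape[-1]
    rows = rows - rows.mean(axis=-1, keepdims=True)
    return np.abs(np.fft.rfft(rows, axis=-1)) ** 2 / m


def raw_periodogram(series: MonthlyTimeSeries) -> Spectrum:
    """Periodogram at Fourier frequencies j/N, j = 0..floor(N/2).

    The series mean is removed before transforming, so the f=0 bin is zero.
    Power is |X_j|^2 / N (one-sided, *not* doubled); by Parseval the sum of
    2*P_j over interior bins plus the Nyquist bin (when N is even) equals
    N times the biased sample variance.
    """
    if series.has_gaps:
        raise GapError(
            "series contains gaps; interpolate or trim before spectral analysis"
        )
    n = len(series)
    if n < 4:
        raise InvalidParameterError("need at least 4 points for a periodogram")
    power = _periodogram_rows(series.values[None, :])[0]
    freqs = np.fft.rfftfreq(n)
    return Spectrum(freqs, power, meta={"estimator": "raw", "n": n})


def kz_periodogram(series: MonthlyTimeSeries, m: int, k: int = 1) -> Spectrum:
    """Averaged periodogram over all N-m+1 overlapping length-m sub-windows.

    Each sub-window is demeaned individually (local trend leakage is then
    bounded by the window, not the record) before its periodogram is taken;
    the estimates are averaged bin-wise.  Frequencies are j/m, so ``m`` sets
    the resolution.  ``k`` = 1 is the plain averaged periodogram; ``k`` > 1
    applies k-1 extra passes of a 3-bin moving average on log power and is
    experimental — the averaged estimate already carries the variance
    reduction.
    """
    if series.has_gaps:
        raise GapError(
            "series contains gaps; interpolate or trim before spectral analysis"
        )
    n = len(series)
    if m < 4 or m > n:
        raise InvalidParameterError(
            f"sub-window length m={m} must satisfy 4 <= m <= len(series)={n}"
        )
    if k < 1:
        raise InvalidParameterError("k must be a positive integer")
    windows = sliding_window_view(series.values, m)
    power = _periodogram_rows(windows).mean(axis=0)
    for _ in range(k - 1):  # experimental log-scale smoothing iterations
        logp = np.log(power + 1e-300)
        kernel = np.ones(3) / 3.0
        smoothed = np.convolve(logp, kernel, mode="same")
        smoothed[0] = logp[0]
        smoothed[-1] = logp[-1]
        power = np.exp(smoothed)
    freqs = np.fft.rfftfreq(m)
    return Spectrum(
        freqs, power, meta={"estimator": "kzp", "m": m, "k": k, "n_windows": n - m + 1}
    )


def dz_smooth(spec: Spectrum, c: float) -> Spectrum:
    """Adaptive smoothing: average over the widest span holding <= c of total power.

    At each bin i the half-span h(i) is the largest h such that the power in
    [i-h, i+h] (truncated at the boundaries) does not exceed ``c`` times the
    total power of the spectrum; the output at i is the mean over that span.
    Where even the single bin exceeds the budget (a dominant peak), h(i)=0
    and the bin passes through unchanged.  Output length equals input length,
    and every output value lies between min(power) and max(power).
    """
    if not 0.0 < c <= 1.0:
        raise InvalidParameterError(f"smoothing fraction c must be in (0, 1], got {c}")
    if len(spec) == 0:
        raise InvalidParameterError("spectrum is empty")
    p = spec.power
    n = p.size
    spans = dz_half_spans(p, c)
    out = np.empty(n)
    for i, h in enumerate(spans):
        a, b = max(0, i - h), min(n, i + h + 1)
        out[i] = p[a:b].mean()
    meta = dict(spec.meta)
    meta["dz_c"] = c
    return Spectrum(spec.freqs, out, meta=meta)


def dz_half_spans(power: np.ndarray, c: float) -> np.ndarray:
    """Half-span h(i) used by :func:`dz_smooth` at each bin.

    h(i) is the largest h with sum(power[i-h : i+h+1]) <= c * sum(power)
    (window truncated at the boundaries), or 0 when even the single bin
    exceeds the budget.  h(i) is nondecreasing in c.
    """
    p = np.asarray(power, dtype=float)
    n = p.size
    budget = c * p.sum()
    cum = np.concatenate([[0.0], np.cumsum(p)])

    def enclosed(i: int, h: int) -> float:
        return cum[min(n, i + h + 1)] - cum[max(0, i - h)]

    spans = np.zeros(n, dtype=int)
    for i in range(n):
        if enclosed(i, 0) > budget:
            continue
        lo_h, hi_h = 0, n
        while lo_h < hi_h:
            mid = (lo_h + hi_h + 1) // 2
            if enclosed(i, mid) <= budget:
                lo_h = mid
            else:
                hi_h = mid - 1
        spans[i] = lo_h
    return spans


def dominant_frequency(spec: Spectrum, band: tuple[float, float]) -> tuple[float, float]:
    """(frequency, power) of the largest bin inside ``band`` (inclusive).

    Ties break toward the lower frequency.  ``band`` is (f_lo, f_hi) in
    cycles per month.
    """
    f_lo, f_hi = band
    if f_lo > f_hi:
        raise InvalidParameterError("band must satisfy f_lo <= f_hi")
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if not mask.any():
        raise InvalidParameterError(
            f"band [{f_lo}, {f_hi}] does not overlap the spectrum"
        )
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(spec.power[idx])]  # argmax returns first max: lower f
    return float(spec.freqs[best]), float(spec.power[best])
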