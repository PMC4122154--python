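"""Kolmogorov-Zurbenko (KZ) iterated moving-average filters.

KZ(k, m) is k iterations of an m-point centred moving average — a low-pass
filter whose transfer function is the m-point Dirichlet kernel raised to the
k-th power, giving strong sidelobe suppression.  For monthly data the
workhorse is the *modified 13-month window*: a 13-point centred average with
half-weighted endpoints, algebraically the convolution of a 12-point and a
2-point uniform average.  It has transfer-function zeros at the annual
frequency 1/12 cycles/month and every harmonic, so two iterations
(KZ(13, 2)) annihilate the seasonal cycle while passing the ~11-year
(132-month) solar-cycle band almost untouched.

All frequencies here are in cycles per month; period in years = 1/(12 f).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .series import MonthlyTimeSeries

__all__ = [
    "KZWindow",
    "uniform_window",
    "modified_13_window",
    "convolve_once",
    "kz_filter",
    "kz_gain",
]

BOUNDARY_POLICIES = ("trim", "shrink")


@dataclass(frozen=True)
class KZWindow:
    """Symmetric, normalised moving-average weights.

    ``weights`` sum to 1 (within 1e-12) and are symmetric about
    ``center_offset`` (the middle index for an odd-length window).
    """

    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size % 2 == 0:
            raise InvalidParameterError("window must be 1-d with odd length")
        if (w < 0).any():
            raise InvalidParameterError("window weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("window weights must sum to 1")
        if not np.allclose(w, w[::-1], rtol=0, atol=1e-15):
            raise InvalidParameterError("window must be symmetric")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size

    @property
    def center_offset(self) -> int:
        return self.weights.size // 2

    @property
    def half_width(self) -> int:
        return self.weights.size // 2

    def self_convolved(self, k: int) -> "KZWindow":
        """The k-fold self-convolution (effective window of KZ(m, k))."""
        if k < 1:
            raise InvalidParameterError("k must be a positive integer")
        w = self.weights
        for _ in range(k - 1):
            w = np.convolve(w, self.weights)
        return KZWindow(w)


def uniform_window(m: int) -> KZWindow:
    """m equal weights 1/m; m must be odd and positive."""
    if m < 1 or m % 2 == 0:
        raise InvalidParameterError(f"window length must be odd and >= 1, got {m}")
    return KZWindow(np.full(m, 1.0 / m))


def modified_13_window() -> KZWindow:
    """13-month centred average with half-weighted endpoints.

    Weights are proportional to [1/2, 1, ..., 1, 1/2]: interior months get
    1/12, the first and last month 1/24.  Identical to the convolution of a
    uniform 12-point with a uniform 2-point window, which is what places
    transfer-function zeros at 1/12 cycles/month and all its harmonics.
    """
    raw = np.ones(13)
    raw[0] = raw[-1] = 0.5
    return KZWindow(raw / raw.sum())


def _check_boundary(boundary: str) -> None:
    if boundary not in BOUNDARY_POLICIES:
        raise InvalidParameterError(
            f"boundary must be one of {BOUNDARY_POLICIES}, got {boundary!r}"
        )


def convolve_once(
    series: MonthlyTimeSeries, window: KZWindow, boundary: str = "trim"
) -> MonthlyTimeSeries:
    """One pass of the moving average.

    boundary="trim"
        Keep only output months whose window lies fully inside the series;
        the result is shorter by ``len(window) - 1`` and its anchor advances
        by the half-width so every output value stays centred on its input
        month.  A NaN gap anywhere inside the window yields a NaN output.
    boundary="shrink"
        Full-length output; near the edges (and across gaps) the weights
        renormalise over the available points, matching common KZ practice.
    """
    _check_boundary(boundary)
    w = window.weights
    vals = series.values
    half = window.half_width
    if boundary == "trim":
        if len(series) < len(window):
            raise InvalidParameterError(
                f"series of length {len(series)} too short for window of "
                f"length {len(window)} under 'trim'; result would be empty"
            )
        out = np.convolve(vals, w, mode="valid")  # symmetric kernel: no flip issue
        return MonthlyTimeSeries(series.start + half, out)
    # shrink: renormalise over non-missing points inside the truncated window
    mask = np.isfinite(vals)
    filled = np.where(mask, vals, 0.0)
    num = np.convolve(filled, w, mode="same")
    den = np.convolve(mask.astype(float), w, mode="same")
    # mode="same" keeps the centre aligned only when the kernel is odd-length
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / den, np.nan)
    return MonthlyTimeSeries(series.start, out)


def kz_filter(
    series: MonthlyTimeSeries,
    window: KZWindow,
    k: int,
    boundary: str = "trim",
) -> MonthlyTimeSeries:
    """KZ(k, m): k successive applications of :func:`convolve_once`.

    Under "trim" the output shrinks by ``k * (len(window) - 1) / 2`` months
    on each end.  Equivalent (on interior points) to a single convolution
    with the k-fold self-convolved window.
    """
    if k < 1:
        raise InvalidParameterError("k must be a positive integer")
    out = series
    for _ in range(k):
        out = convolve_once(out, window, boundary)
    return out


def kz_gain(window: KZWindow, k: int, f) -> np.ndarray | float:
    """Analytic amplitude gain |sum_j w_j exp(-2 pi i f j)|^k at frequency f.

    ``f`` is in cycles per month, scalar or array, and must lie in [0, 0.5].
    For a symmetric window the transfer function is real, so the gain is the
    absolute value of a cosine sum.  For the modified 13-month window this
    equals (|sin(12 pi f) / (12 sin(pi f))| * |cos(pi f)|)^k, with zeros at
    f = h/12 for h = 1..6.
    """
    if k < 1:
        raise InvalidParameterError("k must be a positive integer")
    farr = np.asarray(f, dtype=float)
    if (farr < 0).any() or (farr > 0.5).any():
        raise InvalidParameterError("frequency must lie in [0, 0.5] cycles/month")
    j = np.arange(len(window)) - window.center_offset
    resp = np.abs(np.cos(2 * np.pi * np.multiply.outer(farr, j)) @ window.weights)
    gain = resp**k
    return float(gain) if np.isscalar(f) or farr.ndim == 0 else gain
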