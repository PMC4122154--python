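"""Evenly spaced monthly time series anchored to a calendar month.

``MonthlyTimeSeries`` is the universal currency of the pipeline: index ``i``
always corresponds to calendar month ``start + i`` with no implicit gaps.
Missing observations are represented explicitly as NaN gap markers.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, NoOverlapError

__all__ = ["MonthlyTimeSeries", "month_period"]


def month_period(value) -> pd.Period:
    """Coerce ``value`` (Period, 'YYYY-MM' string, (year, month) tuple,
    datetime-like) to a monthly :class:`pandas.Period`."""
    if isinstance(value, pd.Period):
        if value.freqstr not in ("M", "ME"):
            return value.asfreq("M")
        return value
    if isinstance(value, tuple):
        year, month = value
        return pd.Period(year=int(year), month=int(month), freq="M")
    return pd.Period(value, freq="M")


@dataclass(frozen=True)
class MonthlyTimeSeries:
    """One real observation per consecutive calendar month.

    Parameters
    ----------
    start
        Calendar anchor of index 0 (anything :func:`month_period` accepts).
    values
        Ordered observations; NaN marks an explicit gap. Length >= 1.
    """

    start: pd.Period
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", month_period(self.start))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 1:
            raise InvalidParameterError(
                "values must be a one-dimensional array of length >= 1"
            )
        object.__setattr__(self, "values", vals)

    # -- calendar arithmetic -------------------------------------------------
    def __len__(self) -> int:
        return self.values.size

    @property
    def end(self) -> pd.Period:
        """Calendar month of the last observation."""
        return self.start + (len(self) - 1)

    def periods(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=len(self), freq="M")

    def index_of(self, period) -> int:
        """0-based index of a calendar month (may fall outside the series)."""
        return (month_period(period) - self.start).n

    def value_at(self, period) -> float:
        i = self.index_of(period)
        if not 0 <= i < len(self):
            raise InvalidParameterError(f"{period} outside series span")
        return float(self.values[i])

    @property
    def has_gaps(self) -> bool:
        return bool(np.isnan(self.values).any())

    # -- derived series ------------------------------------------------------
    def crop(self, start=None, end=None) -> "MonthlyTimeSeries":
        """Restrict to the calendar window [start, end] (inclusive)."""
        lo = self.start if start is None else month_period(start)
        hi = self.end if end is None else month_period(end)
        i0 = max(0, (lo - self.start).n)
        i1 = min(len(self), (hi - self.start).n + 1)
        if i1 <= i0:
            raise NoOverlapError(
                f"window {lo}..{hi} does not overlap series {self.start}..{self.end}"
            )
        return MonthlyTimeSeries(self.start + i0, self.values[i0:i1])

    def with_values(self, values: np.ndarray) -> "MonthlyTimeSeries":
        """Same anchor, new values (must keep the length)."""
        vals = np.asarray(values, dtype=float)
        if vals.shape != self.values.shape:
            raise InvalidParameterError("with_values must preserve length")
        return MonthlyTimeSeries(self.start, vals)

    def to_frame(self) -> pd.DataFrame:
        """Two-column frame (``date`` as 'YYYY-MM' strings, ``value``)."""
        return pd.DataFrame(
            {"date": self.periods().astype(str), "value": self.values}
        )

    def __eq__(self, other) -> bool:  # value equality incl. NaN positions
        if not isinstance(other, MonthlyTimeSeries):
            return NotImplemented
        return self.start == other.start and np.array_equal(
            self.values, other.values, equal_nan=True
        )
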