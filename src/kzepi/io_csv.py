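"""CSV readers and writers for the three supported dialects.

* ``sunspot`` — SIDC-style monthly records: columns ``year``, ``month``,
  ``value`` (extra columns ignored; names remappable via ``column_map``).
  The record must be complete: a missing month is an error.
* ``generic`` — one row per month: ``date`` ("YYYY-MM" or "YYYY-MM-DD") and
  ``value``; missing months become explicit NaN gaps, an empty value field
  is a gap in place.
* ``events`` — one ISO date ("YYYY-MM-DD") per row, aggregated to monthly
  counts.

All readers reject malformed rows with line-numbered errors unless
``on_bad_row="skip"``; duplicate months and non-monotone dates are always
errors.
"""
from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CsvFormatError, EmptyInputError, InvalidParameterError
from .preprocess import aggregate_monthly
from .series import MonthlyTimeSeries

__all__ = ["read_monthly_csv", "write_monthly_csv"]

DIALECTS = ("sunspot", "generic", "events")


def _rows(path) -> list[tuple[int, dict]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise EmptyInputError(f"{path}: empty file")
        return [(i, row) for i, row in enumerate(reader, start=2)]  # 1 = header


def _parse_month(text: str, lineno: int) -> pd.Period:
    try:
        return pd.Period(text.strip(), freq="M")
    except Exception as exc:
        raise CsvFormatError(f"line {lineno}: unparseable date {text!r}") from exc


def _check_order(periods: list[pd.Period], lines: list[int]) -> None:
    seen: dict[pd.Period, int] = {}
    prev = None
    for p, ln in zip(periods, lines):
        if p in seen:
            raise CsvFormatError(
                f"line {ln}: duplicate month {p} (first at line {seen[p]})"
            )
        if prev is not None and p < prev:
            raise CsvFormatError(f"line {ln}: non-monotone date {p} after {prev}")
        seen[p] = ln
        prev = p


def read_monthly_csv(
    path,
    dialect: str = "generic",
    column_map: dict | None = None,
    on_bad_row: str = "fail",
) -> MonthlyTimeSeries:
    """Read one monthly series from ``path`` in the given dialect."""
    if dialect not in DIALECTS:
        raise InvalidParameterError(f"dialect must be one of {DIALECTS}")
    if on_bad_row not in ("fail", "skip"):
        raise InvalidParameterError("on_bad_row must be 'fail' or 'skip'")
    cmap = column_map or {}
    rows = _rows(path)
    if not rows:
        raise EmptyInputError(f"{path}: no data rows")

    if dialect == "events":
        dates = []
        for ln, row in rows:
            raw = row.get(cmap.get("date", "date")) or next(iter(row.values()))
            try:
                dates.append(pd.Timestamp(raw.strip()))
            except Exception:
                if on_bad_row == "fail":
                    raise CsvFormatError(f"line {ln}: unparseable event date {raw!r}")
        if not dates:
            raise EmptyInputError(f"{path}: no parseable event dates")
        return aggregate_monthly(dates)

    periods: list[pd.Period] = []
    values: list[float] = []
    lines: list[int] = []
    for ln, row in rows:
        try:
            if dialect == "sunspot":
                year = int(row[cmap.get("year", "year")])
                month = int(row[cmap.get("month", "month")])
                period = pd.Period(year=year, month=month, freq="M")
            else:
                period = _parse_month(row[cmap.get("date", "date")], ln)
            raw_val = row[cmap.get("value", "value")]
            if raw_val is None or raw_val.strip() == "":
                if dialect == "sunspot":
                    raise CsvFormatError(f"line {ln}: missing value in sunspot record")
                val = np.nan
            else:
                val = float(raw_val)
        except CsvFormatError:
            if on_bad_row == "fail":
                raise
            continue
        except (KeyError, TypeError, ValueError) as exc:
            if on_bad_row == "fail":
                raise CsvFormatError(f"line {ln}: malformed row ({exc})") from exc
            continue
        periods.append(period)
        values.append(val)
        lines.append(ln)
    if not periods:
        raise EmptyInputError(f"{path}: no valid rows")
    _check_order(periods, lines)

    full = pd.period_range(periods[0], periods[-1], freq="M")
    if len(full) != len(periods):
        if dialect == "sunspot":
            missing = sorted(set(full) - set(periods))[0]
            raise CsvFormatError(
                f"sunspot record must be complete; month {missing} is missing"
            )
        filled = pd.Series(values, index=pd.PeriodIndex(periods, freq="M"))
        filled = filled.reindex(full)  # absent months -> NaN gap markers
        return MonthlyTimeSeries(full[0], filled.to_numpy())
    return MonthlyTimeSeries(full[0], np.asarray(values, dtype=float))


def write_monthly_csv(series: MonthlyTimeSeries, path) -> None:
    """Write in the ``generic`` dialect; gaps become empty value fields."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "value"])
        for period, value in zip(series.periods(), series.values):
            writer.writerow([str(period), "" if np.isnan(value) else repr(float(value))])
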