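"""Small date and rounding helpers shared across modules."""

from __future__ import annotations

import datetime as dt
import math

import pandas as pd
from dateutil.relativedelta import relativedelta


def add_years(day: dt.date, years: int) -> dt.date:
    """Calendar-accurate anniversary; Feb 29 maps to Feb 28 in non-leap years."""
    return day + relativedelta(years=years)


def add_years_series(dates: pd.Series, years: int) -> pd.Series:
    """Vectorised :func:`add_years` over a datetime64 Series.

    Feb 29 birthdays fall back to Feb 28, matching dateutil's scalar behaviour.
    """
    parts = pd.DataFrame(
        {
            "year": dates.dt.year + years,
            "month": dates.dt.month,
            "day": dates.dt.day,
        }
    )
    out = pd.to_datetime(parts, errors="coerce")
    bad = out.isna() & dates.notna()
    if bad.any():
        parts.loc[bad, "day"] = 28
        out[bad] = pd.to_datetime(parts.loc[bad])
    return out


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (report-table convention, unlike banker's rounding)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def merge_intervals(
    intervals: list[tuple[dt.date, dt.date]],
) -> list[tuple[dt.date, dt.date]]:
    """Merge overlapping or touching closed [start, end] date intervals."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [ordered[0]]
    for start, end in ordered[1:]:
        last_start, last_end = merged[-1]
        if start <= last_end + dt.timedelta(days=1):
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def day_count(start: dt.date, end: dt.date) -> int:
    """Inclusive day count of the closed interval [start, end]."""
    return (end - start).days + 1
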