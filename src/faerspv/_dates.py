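"""Partial-precision date handling for FAERS date-int fields.

FAERS dates (FDA_DT, EVENT_DT, START_DT) are digit strings of length 8
(YYYYMMDD), 6 (YYYYMM) or 4 (YYYY). Partial dates are retained with their
precision rather than padded, because the time-to-onset stage must exclude
them rather than silently treat them as day-precision values.
"""

from __future__ import annotations

import datetime
import re

_DATE_RE = re.compile(r"^\d{4}(\d{2})?(\d{2})?$")

YEAR = "year"
MONTH = "month"
DAY = "day"


def validate_date(raw: str) -> str | None:
    """Return the normalized digit string, '' for absent, None if malformed.

    A malformed date is anything that is not 4/6/8 digits or whose month/day
    components do not form a real calendar value.
    """
    s = raw.strip()
    if not s:
        return ""
    if not _DATE_RE.match(s):
        return None
    year = int(s[:4])
    if not 1900 <= year <= 2100:
        return None
    if len(s) >= 6:
        month = int(s[4:6])
        if not 1 <= month <= 12:
            return None
    if len(s) == 8:
        try:
            datetime.date(year, int(s[4:6]), int(s[6:8]))
        except ValueError:
            return None
    return s


def precision(raw: str) -> str | None:
    """Precision of a validated date string ('' -> None)."""
    if not raw:
        return None
    return {4: YEAR, 6: MONTH, 8: DAY}[len(raw)]


def is_full(raw: str) -> bool:
    """True when the date carries full day precision."""
    return len(raw) == 8


def to_date(raw: str) -> datetime.date:
    """Convert a full-precision date string to a datetime.date."""
    if not is_full(raw):
        raise ValueError(f"not a full-precision date: {raw!r}")
    return datetime.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))


def days_between(start: str, event: str) -> int:
    """Calendar-day difference event - start for full-precision dates."""
    return (to_date(event) - to_date(start)).days


def sort_key(raw: str) -> int:
    """Chronological sort key; partial dates order by their known prefix,
    absent dates sort first."""
    if not raw:
        return -1
    return int(raw.ljust(8, "0"))


def date_to_str(d: datetime.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"
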