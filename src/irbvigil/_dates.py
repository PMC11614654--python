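"""Calendar-date parsing with explicit precision tracking.

Spontaneous-report databases carry partial dates (year-only or
year-month) in the same columns as full dates.  Time-to-onset analysis
must distinguish a genuinely day-precise date from a padded one, so
every parsed date carries a precision tag instead of being silently
coerced.
"""

from __future__ import annotations

import datetime as _dt
from typing import NamedTuple

DAY = "day"
MONTH = "month"
YEAR = "year"
MISSING = "missing"


class ParsedDate(NamedTuple):
    date: _dt.date | None  # anchored to the first day of the period for partial dates
    precision: str  # one of DAY, MONTH, YEAR, MISSING


def parse_date(raw) -> ParsedDate:
    """Parse a FAERS/JADER-style date string into (date, precision).

    Accepted shapes: ``YYYYMMDD`` (day precision), ``YYYYMM`` (month),
    ``YYYY`` (year), and the hyphenated ``YYYY-MM-DD`` / ``YYYY/MM/DD``
    variants JADER exports use.  An invalid calendar day (e.g. Feb 30)
    or anything unparseable maps to (None, "missing").
    """
    if raw is None:
        return ParsedDate(None, MISSING)
    s = str(raw).strip().replace("-", "").replace("/", "").replace(".", "")
    if not s or s.lower() in {"nan", "none", "nat"}:
        return ParsedDate(None, MISSING)
    if not s.isdigit():
        return ParsedDate(None, MISSING)
    try:
        if len(s) == 8:
            return ParsedDate(_dt.date(int(s[:4]), int(s[4:6]), int(s[6:8])), DAY)
        if len(s) == 6:
            return ParsedDate(_dt.date(int(s[:4]), int(s[4:6]), 1), MONTH)
        if len(s) == 4:
            return ParsedDate(_dt.date(int(s), 1, 1), YEAR)
    except ValueError:
        # calendar-invalid (month 13, day 30 of Feb, ...) -> treat as missing
        return ParsedDate(None, MISSING)
    return ParsedDate(None, MISSING)
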