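"""Calendar-month arithmetic.

Japanese outpatient claims record diagnoses at month resolution only, so the
whole phenotyping algorithm runs on a month index: an integer count of months
since January of year 0.  ``YearMonth`` is a thin ordered wrapper around that
integer; differences of two ``YearMonth`` values are calendar-month
separations, and adding an integer shifts by that many months.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass
from functools import total_ordering

_YM_RE = re.compile(r"^(\d{4})-(\d{2})$")


@total_ordering
@dataclass(frozen=True)
class YearMonth:
    """A calendar month, stored as months since 0000-01.

    The encoding ``value = 12*year + (month - 1)`` is bijective with
    ``(year, month)`` pairs, orders identically to the calendar, and makes the
    difference of two instances equal their separation in months.
    """

    value: int

    @classmethod
    def of(cls, year: int, month: int) -> "YearMonth":
        if not 1 <= month <= 12:
            raise ValueError(f"month out of range: {month}")
        return cls(12 * year + (month - 1))

    @classmethod
    def parse(cls, text: str) -> "YearMonth":
        """Parse an ISO ``YYYY-MM`` string."""
        m = _YM_RE.match(text.strip())
        if not m:
            raise ValueError(f"not a YYYY-MM month: {text!r}")
        return cls.of(int(m.group(1)), int(m.group(2)))

    @property
    def year(self) -> int:
        return self.value // 12

    @property
    def month(self) -> int:
        return self.value % 12 + 1

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"

    def __lt__(self, other: "YearMonth") -> bool:
        return self.value < other.value

    def __add__(self, months: int) -> "YearMonth":
        return YearMonth(self.value + int(months))

    def __sub__(self, other):
        if isinstance(other, YearMonth):
            return self.value - other.value
        return YearMonth(self.value - int(other))

    def first_day(self) -> _dt.date:
        return _dt.date(self.year, self.month, 1)

    def day(self, d: int) -> _dt.date:
        return _dt.date(self.year, self.month, d)


def ym(year: int, month: int) -> YearMonth:
    """Shorthand constructor."""
    return YearMonth.of(year, month)


def month_of(date: _dt.date) -> YearMonth:
    return YearMonth.of(date.year, date.month)


def month_window(anchor: YearMonth, start_offset: int, end_offset: int) -> tuple[YearMonth, YearMonth]:
    """Inclusive month interval ``[anchor+start_offset, anchor+end_offset]``.

    All month windows in the pipeline are closed on both ends.
    """
    if start_offset > end_offset:
        raise ValueError("start_offset must not exceed end_offset")
    return (anchor + start_offset, anchor + end_offset)


def months_in(window: tuple[YearMonth, YearMonth]) -> list[YearMonth]:
    lo, hi = window
    return [YearMonth(v) for v in range(lo.value, hi.value + 1)]
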