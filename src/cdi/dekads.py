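"""Dekad calendar arithmetic.

The dekad (10-day period) is the temporal unit of the Combined Drought
Indicator.  Every month is split into exactly three dekads: days 1-10,
days 11-20, and day 21 through the end of the month.  A year therefore
always contains 36 dekads, and individual dekads span 8, 9, 10 or 11
calendar days depending on the month.
"""

from __future__ import annotations

import calendar as _pycal
import datetime as _dt
from dataclasses import dataclass
from functools import total_ordering


@total_ordering
@dataclass(frozen=True)
class Dekad:
    """One of the 36 ten-day periods of a year.

    Parameters
    ----------
    year : int
        Calendar year (>= 1).
    ordinal : int
        Dekad-of-year in 1..36, numbered ``3 * (month - 1) + dekad_of_month``.
    """

    year: int
    ordinal: int

    def __post_init__(self) -> None:
        if self.year < 1:
            raise ValueError(f"year must be >= 1, got {self.year}")
        if not 1 <= self.ordinal <= 36:
            raise ValueError(f"ordinal must be in 1..36, got {self.ordinal}")

    # ------------------------------------------------------------------
    # constructors
    # ------------------------------------------------------------------
    @classmethod
    def from_month(cls, year: int, month: int, dekad_of_month: int) -> "Dekad":
        if not 1 <= month <= 12:
            raise ValueError(f"month must be in 1..12, got {month}")
        if not 1 <= dekad_of_month <= 3:
            raise ValueError(f"dekad_of_month must be in 1..3, got {dekad_of_month}")
        return cls(year, 3 * (month - 1) + dekad_of_month)

    @classmethod
    def from_date(cls, date: _dt.date) -> "Dekad":
        """The unique dekad whose day span contains ``date``."""
        dom = min((date.day - 1) // 10, 2) + 1
        return cls.from_month(date.year, date.month, dom)

    # ------------------------------------------------------------------
    # structure
    # ------------------------------------------------------------------
    @property
    def month(self) -> int:
        return (self.ordinal - 1) // 3 + 1

    @property
    def dekad_of_month(self) -> int:
        return (self.ordinal - 1) % 3 + 1

    @property
    def start_date(self) -> _dt.date:
        return _dt.date(self.year, self.month, 10 * (self.dekad_of_month - 1) + 1)

    @property
    def end_date(self) -> _dt.date:
        if self.dekad_of_month < 3:
            return _dt.date(self.year, self.month, 10 * self.dekad_of_month)
        last = _pycal.monthrange(self.year, self.month)[1]
        return _dt.date(self.year, self.month, last)

    @property
    def day_count(self) -> int:
        """Number of days N spanned by this dekad (8..11)."""
        return (self.end_date - self.start_date).days + 1

    def days(self) -> list[_dt.date]:
        d0 = self.start_date
        return [d0 + _dt.timedelta(days=k) for k in range(self.day_count)]

    @property
    def midpoint(self) -> _dt.datetime:
        """Temporal midpoint of the day span (used for compositing weights)."""
        start = _dt.datetime.combine(self.start_date, _dt.time())
        return start + _dt.timedelta(days=self.day_count / 2.0)

    # ------------------------------------------------------------------
    # navigation
    # ------------------------------------------------------------------
    def previous(self) -> "Dekad":
        if self.ordinal == 1:
            return Dekad(self.year - 1, 36)
        return Dekad(self.year, self.ordinal - 1)

    def next(self) -> "Dekad":
        if self.ordinal == 36:
            return Dekad(self.year + 1, 1)
        return Dekad(self.year, self.ordinal + 1)

    def __lt__(self, other: "Dekad") -> bool:
        return (self.year, self.ordinal) < (other.year, other.ordinal)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Dekad({self.year}, {self.ordinal:02d})"


def dekads_in_year(year: int) -> list[Dekad]:
    """All 36 dekads of ``year`` in calendar order."""
    return [Dekad(year, t) for t in range(1, 37)]


def dekad_of_date(date: _dt.date) -> Dekad:
    """Map a calendar date to its dekad."""
    return Dekad.from_date(date)


def dekad_range(first: Dekad, last: Dekad) -> list[Dekad]:
    """Inclusive sequence of dekads from ``first`` to ``last``."""
    if last < first:
        raise ValueError("last dekad precedes first")
    out = [first]
    while out[-1] < last:
        out.append(out[-1].next())
    return out
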