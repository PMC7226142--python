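"""Partial calendar dates as they occur in spontaneous-report databases.

FAERS date fields are plain digit strings of 4, 6 or 8 characters
(``YYYY``, ``YYYYMM``, ``YYYYMMDD``); any of the three precisions may
appear in the same column.  Day-level arithmetic (time-to-onset,
aberrant-report checks) is only valid on full-precision dates, so the
precision is carried explicitly instead of being coerced to a day.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass
from typing import Optional

__all__ = ["PartialDate", "parse_partial_date"]


@dataclass(frozen=True, order=True)
class PartialDate:
    """A calendar date known to year, month or day precision."""

    year: int
    month: Optional[int] = None
    day: Optional[int] = None

    def __post_init__(self) -> None:
        if self.day is not None and self.month is None:
            raise ValueError("day given without month")

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    @property
    def is_full(self) -> bool:
        return self.day is not None

    def to_date(self) -> _dt.date:
        """Convert to :class:`datetime.date`; requires day precision."""
        if not self.is_full:
            raise ValueError(f"date {self} has {self.precision} precision only")
        return _dt.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    @classmethod
    def from_date(cls, d: _dt.date) -> "PartialDate":
        return cls(d.year, d.month, d.day)

    def isoformat(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}-{self.month:02d}-{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}-{self.month:02d}"
        return f"{self.year:04d}"

    def compact(self) -> str:
        """Digit-string form (``YYYY``/``YYYYMM``/``YYYYMMDD``)."""
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


def parse_partial_date(text: object) -> Optional[PartialDate]:
    """Parse a FAERS-style digit date string.

    Returns ``None`` for empty/missing input.  Non-digit input, an
    unexpected length, or an impossible calendar value (month 13,
    February 30, ...) also yields ``None``, with a warning, so that a
    single malformed field never aborts a multi-million-row load.
    """
    if text is None:
        return None
    s = str(text).strip()
    if not s or s.lower() in {"nan", "none"}:
        return None
    if not s.isdigit() or len(s) not in (4, 6, 8):
        warnings.warn(f"unparseable date {s!r} treated as missing", stacklevel=2)
        return None
    year = int(s[:4])
    if year < 1900 or year > 2100:
        warnings.warn(f"implausible year in date {s!r} treated as missing", stacklevel=2)
        return None
    if len(s) == 4:
        return PartialDate(year)
    month = int(s[4:6])
    if not 1 <= month <= 12:
        warnings.warn(f"impossible month in date {s!r} treated as missing", stacklevel=2)
        return None
    if len(s) == 6:
        return PartialDate(year, month)
    day = int(s[6:8])
    try:
        _dt.date(year, month, day)
    except ValueError:
        warnings.warn(f"impossible day in date {s!r} treated as missing", stacklevel=2)
        return None
    return PartialDate(year, month, day)
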