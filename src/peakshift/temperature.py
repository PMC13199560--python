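"""Date-indexed daily-mean temperature series.

The single environmental driver of the whole pipeline: one mean air
temperature (deg C) per calendar day, contiguous, no gaps.  Dates are whole
days throughout the package; there is no sub-daily resolution.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

__all__ = ["TemperatureSeries", "CoverageError"]

ONE_DAY = dt.timedelta(days=1)


class CoverageError(KeyError):
    """A date fell outside the contiguous coverage of a TemperatureSeries."""


@dataclass(frozen=True)
class TemperatureSeries:
    """Contiguous daily-mean temperatures starting at ``start``.

    Parameters
    ----------
    start
        Calendar date of the first value.
    values
        Daily mean temperatures in deg C, one per day, all finite.
    """

    start: dt.date
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("temperature series must be a nonempty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("temperature series contains non-finite values")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def end(self) -> dt.date:
        """Last covered date (inclusive)."""
        return self.start + dt.timedelta(days=len(self) - 1)

    def covers(self, day: dt.date) -> bool:
        return self.start <= day <= self.end

    def index_of(self, day: dt.date) -> int:
        if not self.covers(day):
            raise CoverageError(
                f"date {day.isoformat()} outside series coverage "
                f"[{self.start.isoformat()}, {self.end.isoformat()}]"
            )
        return (day - self.start).days

    def value_on(self, day: dt.date) -> float:
        return float(self.values[self.index_of(day)])

    def date_at(self, index: int) -> dt.date:
        if not 0 <= index < len(self):
            raise IndexError(index)
        return self.start + dt.timedelta(days=index)

    def window(self, first: dt.date, last: dt.date) -> np.ndarray:
        """Values on the inclusive date window [first, last]."""
        if last < first:
            raise ValueError(f"empty window: {first} > {last}")
        return self.values[self.index_of(first) : self.index_of(last) + 1]

    def dates(self) -> list[dt.date]:
        return [self.start + dt.timedelta(days=i) for i in range(len(self))]

    @classmethod
    def constant(cls, start: dt.date, n_days: int, temp_c: float) -> "TemperatureSeries":
        """Series of ``n_days`` identical values — handy for analytic checks."""
        return cls(start, np.full(n_days, float(temp_c)))

    def plus(self, delta: np.ndarray | float) -> "TemperatureSeries":
        """New series with ``delta`` (scalar or per-day array) added."""
        return TemperatureSeries(self.start, self.values + delta)
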