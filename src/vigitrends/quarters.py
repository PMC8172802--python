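"""Calendar-quarter labels and quarter-indexed series.

Quarters are labelled ``"YYYYQn"`` with n in 1..4 and ordered by the integer
index ``year * 4 + (n - 1)``, so quarter arithmetic is plain integer
arithmetic.  The study window 2007Q1-2020Q2 spans 54 quarters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

#: Inclusive default analysis window.
DEFAULT_WINDOW = ("2007Q1", "2020Q2")


def parse_quarter(label: str) -> int:
    """Return the integer index of a ``"YYYYQn"`` label.

    Raises
    ------
    ValueError
        If the label is not a well-formed quarter.
    """
    m = QUARTER_RE.match(str(label).strip())
    if not m:
        raise ValueError(f"malformed quarter label: {label!r} (expected 'YYYYQn')")
    year, q = int(m.group(1)), int(m.group(2))
    return year * 4 + (q - 1)


def format_quarter(index: int) -> str:
    """Inverse of :func:`parse_quarter`."""
    year, q = divmod(int(index), 4)
    return f"{year}Q{q + 1}"


def quarter_range(start: str, end: str) -> list[str]:
    """Inclusive list of quarter labels from *start* to *end*."""
    i, j = parse_quarter(start), parse_quarter(end)
    if i > j:
        raise ValueError(f"window start {start!r} is after end {end!r}")
    return [format_quarter(k) for k in range(i, j + 1)]


def month_to_quarter(period: str) -> str:
    """Map a monthly period ``"YYYY-MM"`` to its quarter label.

    Quarter labels pass through unchanged, so ingest code can accept both.
    """
    period = str(period).strip()
    if QUARTER_RE.match(period):
        return period
    m = re.match(r"^(\d{4})-(\d{2})$", period)
    if not m:
        raise ValueError(f"malformed period: {period!r} (expected 'YYYYQn' or 'YYYY-MM')")
    year, month = int(m.group(1)), int(m.group(2))
    if not 1 <= month <= 12:
        raise ValueError(f"malformed period: {period!r} (month out of range)")
    return f"{year}Q{(month - 1) // 3 + 1}"


@dataclass(frozen=True)
class QuarterSeries:
    """One value per quarter; missing values are NaN.

    Invariants: quarter labels strictly increasing, one value per quarter.
    """

    quarters: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(self.quarters) != vals.shape[0]:
            raise ValueError(
                f"{len(self.quarters)} quarters but {vals.shape[0]} values"
            )
        idx = [parse_quarter(q) for q in self.quarters]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("quarter labels must be strictly increasing")

    def __len__(self) -> int:
        return len(self.quarters)

    @classmethod
    def from_window(cls, start: str, end: str, mapping: dict[str, float]) -> "QuarterSeries":
        """Zero-filled series over an inclusive window, overridden by *mapping*."""
        quarters = quarter_range(start, end)
        return cls(tuple(quarters), np.array([mapping.get(q, 0.0) for q in quarters]))

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.quarters, self.values.tolist()))
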