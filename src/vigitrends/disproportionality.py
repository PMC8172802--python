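"""Reporting odds ratio (ROR) disproportionality and the signal criterion.

For one drug and one event-term category the spontaneous-report database is
collapsed to a 2x2 table of report counts::

                    category      no category
    drug               a               b
    no drug            c               d

ROR = (a*d)/(b*c); its 95% CI uses the Woolf log-normal interval
``exp(ln ROR +/- z*sqrt(1/a + 1/b + 1/c + 1/d))`` with z = 1.96.  A pair is a
safety signal when the co-report count a exceeds 3 and the CI lower bound
exceeds 1 (both strict).

No Haldane-Anscombe continuity correction is applied by default; pass
``continuity_correction=True`` to add 0.5 to every cell when some cell is
zero.  Reported values are rounded half-even to 2 decimal places by
:func:`round_result`; internal computation is at full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .quarters import QuarterSeries, quarter_range
from .vocab import TermCategory

__all__ = [
    "ContingencyTable",
    "SignalResult",
    "table_from_marginals",
    "compute_ror",
    "detect_signal",
    "ror_table",
    "quarterly_ror_series",
    "load_marginals_fixture",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 report counts: a = drug & category, b = drug only, c = category only, d = neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n < 1:
            raise ValueError("contingency table must contain at least one report")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalResult:
    """ROR with its 95% CI, the co-report count, and the signal flag.

    ``ci_available`` is False when a zero cell makes the log-scale interval
    undefined; ``ci_low``/``ci_high`` are then NaN and ``is_signal`` False.
    """

    ror: float
    ci_low: float
    ci_high: float
    n_combination: int
    is_signal: bool
    ci_available: bool = True


def table_from_marginals(
    n_total: int, n_drug: int, n_category: int, n_combination: int
) -> ContingencyTable:
    """Build the 2x2 table from printed marginal totals.

    a = n_combination, b = n_drug - a, c = n_category - a,
    d = n_total - n_drug - n_category + a.
    """
    if n_combination > n_drug:
        raise ValueError(
            f"inconsistent marginals: n_combination ({n_combination}) > n_drug ({n_drug})"
        )
    if n_combination > n_category:
        raise ValueError(
            f"inconsistent marginals: n_combination ({n_combination}) > n_category ({n_category})"
        )
    if n_drug + n_category - n_combination > n_total:
        raise ValueError(
            f"inconsistent marginals: n_drug + n_category - n_combination "
            f"({n_drug + n_category - n_combination}) > n_total ({n_total})"
        )
    return ContingencyTable(
        a=n_combination,
        b=n_drug - n_combination,
        c=n_category - n_combination,
        d=n_total - n_drug - n_category + n_combination,
    )


def compute_ror(
    table: ContingencyTable, z: float = 1.96, continuity_correction: bool = False
) -> SignalResult:
    """ROR, Woolf 95% CI and signal flag for one 2x2 table.

    Raises
    ------
    ValueError
        If b or c is zero (ROR undefined) and no continuity correction is
        requested.  A zero a or d with nonzero b, c yields ror 0 or inf with
        the CI flagged unavailable rather than an error.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if continuity_correction and min(table.a, table.b, table.c, table.d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b == 0 or c == 0:
        raise ValueError(f"undefined ROR: zero cell b={table.b} or c={table.c}")
    if a == 0:
        ror = 0.0
    elif d == 0:
        ror = math.inf
    else:
        ror = (a * d) / (b * c)
    if a > 0 and d > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        ci_low = math.exp(math.log(ror) - z * se)
        ci_high = math.exp(math.log(ror) + z * se)
        ci_available = True
        is_signal = table.a > 3 and ci_low > 1
    else:
        ci_low = ci_high = math.nan
        ci_available = False
        is_signal = False
    return SignalResult(
        ror=ror,
        ci_low=ci_low,
        ci_high=ci_high,
        n_combination=table.a,
        is_signal=is_signal,
        ci_available=ci_available,
    )


def detect_signal(result: SignalResult) -> bool:
    """Signal rule: co-report count > 3 and CI lower bound > 1, both strict."""
    if not result.ci_available:
        raise ValueError("signal rule requires an available confidence interval")
    return result.n_combination > 3 and result.ci_low > 1


def round_result(result: SignalResult, ndigits: int = 2) -> SignalResult:
    """Round ror/ci_low/ci_high half-even for reporting."""
    return replace(
        result,
        ror=round(result.ror, ndigits),
        ci_low=round(result.ci_low, ndigits),
        ci_high=round(result.ci_high, ndigits),
    )


MarginalsLike = Union[pd.DataFrame, Mapping[tuple[str, str], ContingencyTable]]


def _tables_from_marginals_frame(frame: pd.DataFrame) -> dict[tuple[str, str], ContingencyTable]:
    required = {"drug", "category", "n_drug", "n_category", "n_combination", "n_total"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"marginals table missing columns: {sorted(missing)}")
    tables = {}
    for row in frame.itertuples(index=False):
        tables[(row.drug, row.category)] = table_from_marginals(
            int(row.n_total), int(row.n_drug), int(row.n_category), int(row.n_combination)
        )
    return tables


def ror_table(
    source,
    drugs: Sequence[str],
    categories: Sequence[Union[str, TermCategory]],
    z: float = 1.96,
    errors: str = "raise",
) -> pd.DataFrame:
    """One SignalResult row per (drug, category), ordered drugs x categories.

    *source* is either a :class:`~vigitrends.report_store.ReportStore`, a
    marginals DataFrame (columns drug, category, n_drug, n_category,
    n_combination, n_total), or a mapping (drug, category) -> ContingencyTable.

    Returns a DataFrame with columns drug, category, n_combination, ror,
    ci_low, ci_high, is_signal (full precision; round for reporting).
    With ``errors="coerce"``, pairs whose ROR is undefined (zero b or c)
    yield NaN statistics and ``is_signal=False`` instead of raising.
    """
    if errors not in ("raise", "coerce"):
        raise ValueError(f"errors must be 'raise' or 'coerce', got {errors!r}")
    from .report_store import ReportStore, count_marginals  # local import: avoids cycle

    cat_names = [c.name if isinstance(c, TermCategory) else c for c in categories]
    if isinstance(source, ReportStore):
        cats = {c.name: c for c in categories if isinstance(c, TermCategory)}
        missing = [n for n in cat_names if n not in cats]
        if missing:
            raise TypeError(f"categories must be TermCategory objects for a store: {missing}")
        tables = {
            (d, n): count_marginals(source, d, cats[n]) for d in drugs for n in cat_names
        }
    elif isinstance(source, pd.DataFrame):
        tables = _tables_from_marginals_frame(source)
    elif isinstance(source, Mapping):
        tables = dict(source)
    else:
        raise TypeError(f"unsupported source type: {type(source).__name__}")

    rows = []
    for d in drugs:
        for n in cat_names:
            if (d, n) not in tables:
                raise KeyError(f"no contingency table for ({d!r}, {n!r})")
            try:
                res = compute_ror(tables[(d, n)], z=z)
            except ValueError:
                if errors == "raise":
                    raise
                res = SignalResult(
                    math.nan, math.nan, math.nan,
                    n_combination=tables[(d, n)].a,
                    is_signal=False, ci_available=False,
                )
            rows.append(
                {
                    "drug": d,
                    "category": n,
                    "n_combination": res.n_combination,
                    "ror": res.ror,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "is_signal": res.is_signal,
                }
            )
    return pd.DataFrame(rows, columns=["drug", "category", "n_combination", "ror", "ci_low", "ci_high", "is_signal"])


def quarterly_ror_series(store, drug: str, category: TermCategory) -> dict[str, SignalResult | None]:
    """Per-quarter ROR within the store window.

    Each quarter's 2x2 table uses only that quarter's reports.  Quarters where
    the ROR or CI is undefined (zero b, c, a or d) yield ``None`` rather than
    an error.
    """
    from .report_store import count_marginals, subset_quarter

    out: dict[str, SignalResult | None] = {}
    for q in quarter_range(*store.window):
        sub = subset_quarter(store, q)
        if sub.n == 0:
            out[q] = None
            continue
        table = count_marginals(sub, drug, category)
        try:
            res = compute_ror(table)
        except ValueError:
            out[q] = None
            continue
        out[q] = res if res.ci_available else None
    return out


def load_marginals_fixture() -> pd.DataFrame:
    """The packaged 2007-2020Q2 marginal counts for the four study drugs.

    Columns: drug, category, n_drug, n_category, n_combination, n_total.
    These are database-wide report totals, per-drug totals, per-category
    totals and co-report counts; they reconstruct every 2x2 table without
    report-level data.
    """
    ref = resources.files("vigitrends").joinpath("data/faers_marginals_2007_2020q2.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def quarterly_ror_values(store, drug: str, category: TermCategory) -> QuarterSeries:
    """Quarterly ROR point estimates as a :class:`QuarterSeries` (NaN when undefined)."""
    series = quarterly_ror_series(store, drug, category)
    quarters = tuple(series)
    values = np.array([series[q].ror if series[q] is not None else np.nan for q in quarters])
    return QuarterSeries(quarters, values)
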