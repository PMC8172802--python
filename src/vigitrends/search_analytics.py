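"""Search-popularity timelines for abuse-related queries.

This module emulates the reporting contract of consumer search-analytics
tools rather than their closed internals: per period, the most popular
related query (the plain drug-name query) is pinned to a search-popularity
score (SPS) of 100 and every other query is scaled proportionally, so an SPS
of 50 means the query was searched half as often as the top query.  Queries
whose share of total related searches falls below 1% are suppressed —
reported as 0 and flagged — mirroring the big-data-only reporting that, in
the study period, left the low-volume negative control without a usable
timeline.  Per-term-set values live on [0, 100]; summing term sets into a
cumulative abuse timeline may legitimately exceed 100.

Monthly input periods are averaged into calendar quarters at ingest
(configurable to sums).
"""

from __future__ import annotations

import csv
import re
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .quarters import QuarterSeries, month_to_quarter, parse_quarter
from .vocab import DrugEntry, QueryTermSet, normalize_term

__all__ = [
    "QueryRecord",
    "SpsSeries",
    "SpsSummary",
    "VolumeFloorResult",
    "DEFAULT_BLOCKLIST",
    "filter_abuse_queries",
    "compute_sps",
    "cumulative_abuse_sps",
    "summarize_sps",
    "apply_volume_floor",
    "read_query_log_csv",
    "write_sps_csv",
]

#: Collocations that contain an abuse term but are unrelated to abuse.
DEFAULT_BLOCKLIST: tuple[str, ...] = ("high blood pressure",)


@dataclass(frozen=True)
class QueryRecord:
    """One aggregated query-volume observation for one period."""

    query: str
    period: str
    count: float
    context_tag: str = "prescription_drug"
    term_sets: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "query", normalize_term(self.query))
        parse_quarter(self.period)
        if self.count < 0:
            raise ValueError(f"negative count for query {self.query!r}")


@dataclass(frozen=True)
class SpsSeries:
    """Per-quarter SPS for one drug and one term set (or a cumulative sum).

    Suppressed points carry value 0 with the ``suppressed`` flag set; quarters
    with no usable reference volume are NaN.
    """

    drug: str
    term_set: str
    quarters: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    suppressed: np.ndarray = field(repr=False)
    cumulative: bool = False

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        supp = np.asarray(self.suppressed, dtype=bool)
        if not (len(self.quarters) == vals.shape[0] == supp.shape[0]):
            raise ValueError("quarters, values and suppressed must have equal length")
        finite = vals[np.isfinite(vals)]
        if finite.size and finite.min() < 0:
            raise ValueError("SPS values must be non-negative")
        if not self.cumulative and finite.size and finite.max() > 100:
            raise ValueError("per-term SPS values must lie in [0, 100]")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "suppressed", supp)

    def as_quarter_series(self) -> QuarterSeries:
        return QuarterSeries(self.quarters, self.values.copy())


def _phrase_pattern(phrase: str) -> re.Pattern:
    # whole-word match of a (possibly multi-word) phrase
    words = [re.escape(w) for w in normalize_term(phrase).split()]
    return re.compile(r"(?<!\w)" + r"\W+".join(words) + r"(?!\w)")


def filter_abuse_queries(
    records: Iterable[QueryRecord],
    drug: DrugEntry,
    term_sets: Sequence[QueryTermSet],
    blocklist: Sequence[str] = DEFAULT_BLOCKLIST,
) -> list[QueryRecord]:
    """Keep abuse-related queries for one drug, tagged by term set.

    A query is kept when it contains the drug's generic or a brand name AND
    at least one term of some term set, and matches no blocklist collocation
    (e.g. "high blood pressure", which contains "high" but is unrelated to
    abuse).  A query may be tagged with several term sets.  Pure filter:
    output is a subset of input, order preserved.
    """
    drug_pats = [_phrase_pattern(n) for n in (drug.generic_name, *drug.brand_names)]
    block_pats = [_phrase_pattern(b) for b in blocklist]
    term_pats = {
        ts.name: [_phrase_pattern(t) for t in ts.search_terms] for ts in term_sets
    }
    kept = []
    for rec in records:
        q = rec.query
        if not any(p.search(q) for p in drug_pats):
            continue
        if any(p.search(q) for p in block_pats):
            continue
        tags = frozenset(
            name for name, pats in term_pats.items() if any(p.search(q) for p in pats)
        )
        if not tags:
            continue
        kept.append(replace(rec, term_sets=tags))
    return kept


def compute_sps(
    records: Iterable[QueryRecord],
    reference_query_counts: Mapping[str, float],
    *,
    total_related_counts: Mapping[str, float] | None = None,
    suppression_share: float = 0.01,
    drug: str = "",
    term_set: str = "",
) -> SpsSeries:
    """Normalise raw volumes to the 0-100 SPS scale against the top query.

    Per period, SPS = 100 * (summed query volume) / (top-query volume); the
    top query is the plain drug-name query whose per-period volumes are given
    in *reference_query_counts*.  Volumes whose share of total related
    searches (*total_related_counts*; defaults to the reference volumes) is
    below *suppression_share* are set to 0 and flagged suppressed.  Periods
    with zero or missing reference volume yield NaN, not a division error.
    Values are capped at 100, the score of the top query itself.
    """
    if total_related_counts is None:
        total_related_counts = reference_query_counts
    volume: dict[str, float] = defaultdict(float)
    for rec in records:
        volume[rec.period] += rec.count
    quarters = sorted(reference_query_counts, key=parse_quarter)
    values = np.empty(len(quarters))
    suppressed = np.zeros(len(quarters), dtype=bool)
    for i, q in enumerate(quarters):
        top = reference_query_counts.get(q, 0.0)
        if top <= 0:
            values[i] = np.nan
            continue
        vol = volume.get(q, 0.0)
        total = total_related_counts.get(q, top)
        if total > 0 and vol / total < suppression_share:
            values[i] = 0.0
            suppressed[i] = True
        else:
            values[i] = min(100.0, 100.0 * vol / top)
    return SpsSeries(drug, term_set, tuple(quarters), values, suppressed)


def cumulative_abuse_sps(series: Sequence[SpsSeries]) -> QuarterSeries:
    """Sum per-term-set SPS series into one cumulative abuse timeline.

    All series must share the drug and quarter window.  Suppressed points
    contribute exactly 0; the sum may exceed 100.  A quarter is NaN only when
    it is NaN in every component.
    """
    if not series:
        raise ValueError("no SPS series to accumulate")
    first = series[0]
    for s in series[1:]:
        if s.drug != first.drug:
            raise ValueError(f"drug mismatch: {s.drug!r} vs {first.drug!r}")
        if s.quarters != first.quarters:
            raise ValueError("quarter window mismatch among SPS series")
    stacked = np.vstack([s.values for s in series])
    all_nan = np.all(np.isnan(stacked), axis=0)
    total = np.nansum(stacked, axis=0)
    total[all_nan] = np.nan
    return QuarterSeries(first.quarters, total)


@dataclass(frozen=True)
class SpsSummary:
    mean: float
    median: float
    q1: float
    q3: float

    @property
    def iqr(self) -> tuple[float, float]:
        return (self.q1, self.q3)


def summarize_sps(series: QuarterSeries | SpsSeries) -> SpsSummary:
    """Mean, median and [Q1, Q3] of a timeline, ignoring missing values.

    Quartiles use linear interpolation.  Raises on an all-missing series.
    """
    values = series.values if isinstance(series, QuarterSeries) else series.values
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("insufficient data: series has no non-missing values")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return SpsSummary(float(values.mean()), float(med), float(q1), float(q3))


@dataclass(frozen=True)
class VolumeFloorResult:
    records: tuple[QueryRecord, ...]
    insufficient_data: bool


def apply_volume_floor(
    records: Iterable[QueryRecord], min_total_volume: float
) -> VolumeFloorResult:
    """Suppress a drug's whole timeline when total abuse-query volume is too low.

    Mirrors big-data-only reporting: if the summed volume over the window is
    below *min_total_volume* (inclusive threshold: exactly at the floor is
    reported), no records are emitted and the insufficient-data flag is set.
    """
    records = tuple(records)
    total = sum(r.count for r in records)
    if total < min_total_volume:
        return VolumeFloorResult((), True)
    return VolumeFloorResult(records, False)


def drug_sps_series(
    records: Iterable[QueryRecord],
    drug: DrugEntry,
    term_sets: Sequence[QueryTermSet],
    blocklist: Sequence[str] = DEFAULT_BLOCKLIST,
    suppression_share: float = 0.01,
    volume_floor: float = 0.0,
) -> tuple[list[SpsSeries], VolumeFloorResult]:
    """Full search-domain pipeline for one drug.

    Identifies the top query (the plain generic- or brand-name query) and
    the total related volume per period, filters and tags abuse queries,
    applies the whole-timeline volume floor, and normalises each term set to
    an :class:`SpsSeries`.  Returns an empty series list with the
    insufficient-data flag set when the drug's abuse-query volume is below
    the floor.
    """
    records = list(records)
    name_queries = drug.all_names
    drug_pats = [_phrase_pattern(n) for n in name_queries]
    reference: dict[str, float] = defaultdict(float)
    related: dict[str, float] = defaultdict(float)
    for rec in records:
        if rec.query in name_queries:
            reference[rec.period] += rec.count
        if any(p.search(rec.query) for p in drug_pats):
            related[rec.period] += rec.count
    abuse = filter_abuse_queries(records, drug, term_sets, blocklist)
    floored = apply_volume_floor(abuse, volume_floor)
    if floored.insufficient_data:
        return [], floored
    series = [
        compute_sps(
            [r for r in floored.records if ts.name in r.term_sets],
            reference,
            total_related_counts=related,
            suppression_share=suppression_share,
            drug=drug.generic_name,
            term_set=ts.name,
        )
        for ts in term_sets
    ]
    return series, floored


def read_query_log_csv(
    path: str | Path, monthly_aggregation: str = "mean"
) -> list[QueryRecord]:
    """Read the query-log CSV (columns query, period, count, context_tag).

    Periods may be quarters ("YYYYQn") or months ("YYYY-MM"); monthly rows of
    the same query are aggregated to quarters by *monthly_aggregation*
    ("mean", the default, or "sum").
    """
    if monthly_aggregation not in ("mean", "sum"):
        raise ValueError(f"monthly_aggregation must be 'mean' or 'sum', got {monthly_aggregation!r}")
    groups: dict[tuple[str, str, str], list[float]] = defaultdict(list)
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            key = (
                normalize_term(row["query"]),
                month_to_quarter(row["period"]),
                row.get("context_tag", "prescription_drug"),
            )
            groups[key].append(float(row["count"]))
    agg = np.mean if monthly_aggregation == "mean" else np.sum
    return [
        QueryRecord(query=q, period=p, count=float(agg(counts)), context_tag=tag)
        for (q, p, tag), counts in groups.items()
    ]


def write_sps_csv(series: Sequence[SpsSeries], path: str | Path) -> None:
    """SPS-series CSV: columns drug, term_set, quarter, sps, suppressed."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug", "term_set", "quarter", "sps", "suppressed"])
        for s in series:
            for q, v, supp in zip(s.quarters, s.values, s.suppressed):
                writer.writerow([s.drug, s.term_set, q, "" if np.isnan(v) else v, int(supp)])
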