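"""Spontaneous adverse-event report collections: cleaning and counting.

A report links one or more drugs to one or more MedDRA event PTs within a
calendar quarter.  Cleaning mirrors standard pharmacovigilance-database
preparation: brand names are normalised to the generic drug name, duplicate
report IDs are dropped (first occurrence kept), and — optionally, on by
default — reports identical in (quarter, drugs, events) but carrying
different IDs are collapsed to one.  All removals are tallied in a cleaning
log so the grand total N is auditable.

Set semantics throughout: a report naming a drug under both its brand and
generic name counts once.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .disproportionality import ContingencyTable
from .quarters import DEFAULT_WINDOW, QuarterSeries, parse_quarter, quarter_range
from .vocab import DrugEntry, TermCategory, normalize_term

__all__ = [
    "AdverseEventReport",
    "CleaningLog",
    "ReportStore",
    "normalize_drug_names",
    "deduplicate",
    "count_marginals",
    "quarterly_counts",
    "subset_quarter",
    "read_reports_csv",
    "read_reports_jsonl",
    "write_reports_csv",
]


@dataclass(frozen=True)
class AdverseEventReport:
    """One spontaneous report: ID, quarter, drug mentions and event PTs."""

    report_id: str
    quarter: str
    drugs: frozenset[str]
    events: frozenset[str]

    def __post_init__(self) -> None:
        parse_quarter(self.quarter)  # raises on malformed label
        drugs = frozenset(normalize_term(d) for d in self.drugs if normalize_term(d))
        events = frozenset(normalize_term(e) for e in self.events if normalize_term(e))
        if not drugs:
            raise ValueError(f"report {self.report_id!r} has no drugs")
        if not events:
            raise ValueError(f"report {self.report_id!r} has no events")
        object.__setattr__(self, "drugs", drugs)
        object.__setattr__(self, "events", events)


@dataclass
class CleaningLog:
    """Counts of records removed at each cleaning stage."""

    n_input: int = 0
    n_id_duplicates: int = 0
    n_content_duplicates: int = 0
    n_out_of_window: int = 0
    n_parse_dropped: int = 0

    @property
    def n_removed(self) -> int:
        return (
            self.n_id_duplicates
            + self.n_content_duplicates
            + self.n_out_of_window
            + self.n_parse_dropped
        )


@dataclass(frozen=True)
class ReportStore:
    """A cleaned report collection over an inclusive quarter window.

    ``known_drugs``, when set, defines the universe of recognised generic
    names: asking for marginals of a drug outside it is an error (a known
    drug simply absent from the reports yields zero counts).
    """

    reports: tuple[AdverseEventReport, ...]
    window: tuple[str, str] = DEFAULT_WINDOW
    cleaning_log: CleaningLog = field(default_factory=CleaningLog, compare=False)
    known_drugs: frozenset[str] | None = None

    def __post_init__(self) -> None:
        lo, hi = parse_quarter(self.window[0]), parse_quarter(self.window[1])
        for r in self.reports:
            q = parse_quarter(r.quarter)
            if not lo <= q <= hi:
                raise ValueError(
                    f"report {r.report_id!r} quarter {r.quarter} outside window {self.window}"
                )

    @property
    def n(self) -> int:
        """Grand total N of reports."""
        return len(self.reports)


def normalize_drug_names(
    report: AdverseEventReport, drugs: Sequence[DrugEntry]
) -> AdverseEventReport:
    """Replace brand names with generic names (case-insensitive).

    Unrecognised names are case-folded and kept.  A report mentioning both
    brand and generic of the same drug collapses to one mention.
    """
    brand_to_generic = {b: d.generic_name for d in drugs for b in d.brand_names}
    mapped = frozenset(brand_to_generic.get(name, name) for name in report.drugs)
    return replace(report, drugs=mapped)


def deduplicate(
    reports: Iterable[AdverseEventReport],
    window: tuple[str, str] = DEFAULT_WINDOW,
    collapse_content_duplicates: bool = True,
    known_drugs: frozenset[str] | None = None,
) -> ReportStore:
    """Clean a report collection into a :class:`ReportStore`.

    Keeps the first occurrence of each report_id; when
    *collapse_content_duplicates* is on (default), reports identical in
    (quarter, drugs, events) under different IDs are also collapsed to the
    first one.  Reports outside *window* are dropped.  All removals are
    counted in the store's cleaning log.  Idempotent.
    """
    log = CleaningLog()
    lo, hi = parse_quarter(window[0]), parse_quarter(window[1])
    seen_ids: set[str] = set()
    seen_content: set[tuple] = set()
    kept: list[AdverseEventReport] = []
    for r in reports:
        log.n_input += 1
        if not lo <= parse_quarter(r.quarter) <= hi:
            log.n_out_of_window += 1
            continue
        if r.report_id in seen_ids:
            log.n_id_duplicates += 1
            continue
        content = (r.quarter, r.drugs, r.events)
        if collapse_content_duplicates and content in seen_content:
            log.n_content_duplicates += 1
            continue
        seen_ids.add(r.report_id)
        seen_content.add(content)
        kept.append(r)
    return ReportStore(tuple(kept), window=window, cleaning_log=log, known_drugs=known_drugs)


def _check_drug(store: ReportStore, drug: str) -> str:
    drug = normalize_term(drug)
    if store.known_drugs is not None and drug not in store.known_drugs:
        raise KeyError(f"unknown drug: {drug!r}")
    return drug


def count_marginals(store: ReportStore, drug: str, category: TermCategory) -> ContingencyTable:
    """The 2x2 table for one drug and one term category over the whole store.

    a counts reports mentioning the drug AND at least one PT of the category;
    b the drug without the category; c the category without the drug; d
    neither.  a+b+c+d equals the store's grand total N exactly.
    """
    if store.n == 0:
        raise ValueError("cannot count marginals of an empty store")
    drug = _check_drug(store, drug)
    pts = category.pt_set
    a = b = c = d = 0
    for r in store.reports:
        has_drug = drug in r.drugs
        has_event = not pts.isdisjoint(r.events)
        if has_drug:
            if has_event:
                a += 1
            else:
                b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def quarterly_counts(store: ReportStore, drug: str, category: TermCategory) -> QuarterSeries:
    """Per-quarter co-report counts of (drug, category), zero-filled over the window.

    The series sums to the ``a`` cell of :func:`count_marginals`.
    """
    drug = _check_drug(store, drug)
    pts = category.pt_set
    counts: dict[str, float] = {}
    for r in store.reports:
        if drug in r.drugs and not pts.isdisjoint(r.events):
            counts[r.quarter] = counts.get(r.quarter, 0.0) + 1.0
    return QuarterSeries.from_window(store.window[0], store.window[1], counts)


def subset_quarter(store: ReportStore, quarter: str) -> ReportStore:
    """The sub-store containing only one quarter's reports (window unchanged)."""
    kept = tuple(r for r in store.reports if r.quarter == quarter)
    return ReportStore(kept, window=store.window, known_drugs=store.known_drugs)


# --- I/O: CSV dialect (drugs/events semicolon-delimited) and JSON lines ---

def _parse_rows(rows: Iterable[dict], log: CleaningLog) -> list[AdverseEventReport]:
    out = []
    for row in rows:
        drugs = row.get("drugs") or []
        events = row.get("events") or []
        if isinstance(drugs, str):
            drugs = [d for d in drugs.split(";") if d.strip()]
        if isinstance(events, str):
            events = [e for e in events.split(";") if e.strip()]
        try:
            out.append(
                AdverseEventReport(
                    report_id=str(row["report_id"]).strip(),
                    quarter=str(row["quarter"]).strip(),
                    drugs=frozenset(drugs),
                    events=frozenset(events),
                )
            )
        except (ValueError, KeyError):
            log.n_parse_dropped += 1
    return out


def read_reports_csv(
    path: str | Path,
    window: tuple[str, str] = DEFAULT_WINDOW,
    collapse_content_duplicates: bool = True,
    known_drugs: frozenset[str] | None = None,
) -> ReportStore:
    """Read the report CSV dialect (columns report_id, quarter, drugs, events;
    drugs/events semicolon-delimited; UTF-8; header required) and clean it.

    Records with missing/blank drugs or events are dropped and logged.
    """
    log = CleaningLog()
    with open(path, newline="", encoding="utf-8") as fh:
        parsed = _parse_rows(csv.DictReader(fh), log)
    store = deduplicate(parsed, window, collapse_content_duplicates, known_drugs)
    store.cleaning_log.n_parse_dropped = log.n_parse_dropped
    store.cleaning_log.n_input += log.n_parse_dropped
    return store


def read_reports_jsonl(
    path: str | Path,
    window: tuple[str, str] = DEFAULT_WINDOW,
    collapse_content_duplicates: bool = True,
    known_drugs: frozenset[str] | None = None,
) -> ReportStore:
    """JSON-lines alternative: one object per line with list-valued drugs/events."""
    log = CleaningLog()
    with open(path, encoding="utf-8") as fh:
        rows = [json.loads(line) for line in fh if line.strip()]
    parsed = _parse_rows(rows, log)
    store = deduplicate(parsed, window, collapse_content_duplicates, known_drugs)
    store.cleaning_log.n_parse_dropped = log.n_parse_dropped
    store.cleaning_log.n_input += log.n_parse_dropped
    return store


def write_reports_csv(store: ReportStore, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["report_id", "quarter", "drugs", "events"])
        for r in store.reports:
            writer.writerow(
                [r.report_id, r.quarter, ";".join(sorted(r.drugs)), ";".join(sorted(r.events))]
            )
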