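"""Synthetic report databases and query logs with closed-form ground truth.

The generator emulates the statistical structure the two-domain method
assumes, so every pipeline stage is testable without external data:

* **Reports.** Per quarter, each report draws independent drug mentions
  (study drugs with configured marginal probabilities, plus filler drugs so
  the b/c/d cells are populated) and event PTs.  A category's event odds are
  ``background_odds * latent_trend(quarter)``, multiplied by the configured
  enrichment factor for every study drug present.  Because enrichment acts
  on the *odds* scale and drug prevalence is constant across quarters, the
  configured multiplier equals the large-sample reporting odds ratio exactly
  — the ground truth is closed-form.
* **Query logs.** Per quarter and drug, a top query (the plain drug name)
  with stable baseline volume, plus abuse-related queries whose log-volume
  follows ``coupling * z(quarter) + sqrt(1-coupling^2) * noise``, where z is
  the standardised log latent trend.  Coupling 1 ties the search domain to
  the same trend that modulates report enrichment (positive cross-domain
  rank correlation); coupling 0 makes the domains independent; the sign of
  the coupling is the expected sign of rho.  Decoy queries (a blocklisted
  collocation and a non-abuse query) exercise the filtering stage.

Everything is driven by one ``numpy`` Generator seeded from the config, so a
fixed config reproduces identical output, byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .quarters import DEFAULT_WINDOW, quarter_range
from .report_store import AdverseEventReport, ReportStore
from .search_analytics import QueryRecord
from .vocab import TermCategory, load_default_vocab

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_reports",
    "generate_query_log",
    "ground_truth",
    "recovery_scenario",
    "null_signal_scenario",
    "coupled_scenario",
    "write_query_log_csv",
]

# Marginal mention probabilities mirroring the observed per-drug report
# shares (per-drug totals over the 7.43M grand total), and background event
# probabilities mirroring the per-category shares.
_DEFAULT_DRUGS = {
    "pregabalin": 0.01452,
    "gabapentin": 0.01378,
    "clonazepam": 0.00752,
    "levetiracetam": 0.00590,
}
_DEFAULT_CATEGORIES = {
    "drug_abuse_and_dependence": 0.01601,
    "drug_withdrawal": 0.00379,
    "overdose": 0.01148,
    "tolerance": 0.00026,
    "euphoria": 0.03770,
}
# Illustrative default enrichment: the aggregate disproportionality pattern
# of the four study drugs (not a re-derivation; a realistic demo setting).
_DEFAULT_ENRICHMENT = {
    "pregabalin": {"drug_abuse_and_dependence": 2.78, "drug_withdrawal": 3.76, "overdose": 1.69, "tolerance": 4.73, "euphoria": 2.87},
    "gabapentin": {"drug_abuse_and_dependence": 1.83, "drug_withdrawal": 2.09, "overdose": 1.65, "tolerance": 3.76, "euphoria": 2.09},
    "levetiracetam": {"drug_abuse_and_dependence": 1.10, "drug_withdrawal": 1.54, "overdose": 1.98, "tolerance": 0.78, "euphoria": 1.27},
    "clonazepam": {"drug_abuse_and_dependence": 4.47, "drug_withdrawal": 4.81, "overdose": 4.29, "tolerance": 6.94, "euphoria": 2.41},
}
_DEFAULT_QUERY_VOLUME = {
    "pregabalin": 50_000.0,
    "gabapentin": 100_000.0,
    "clonazepam": 150_000.0,
    "levetiracetam": 500.0,  # deliberately low: the insufficient-data scenario
}
# Abuse-query share of the top-query volume; mirrors the relative ordering of
# the drugs' cumulative abuse search interest.
_DEFAULT_ABUSE_SHARE = {
    "pregabalin": 0.1125,
    "gabapentin": 0.225,
    "clonazepam": 0.455,
    "levetiracetam": 0.08,
}

_QUERY_TEMPLATES = {
    "drug_abuse_and_dependence": ("{drug} abuse", "{drug} dependence"),
    "drug_withdrawal": ("{drug} withdrawal symptoms",),
    "overdose": ("{drug} overdose",),
    "tolerance": ("{drug} tolerance",),
    "euphoria": ("can you get high of {drug}",),
}


class SimulationConfig(BaseModel):
    """Ground-truth parameters for both synthetic domains.

    ``enrichment[drug][category]`` is the odds multiplier applied to the
    category's event odds when the drug is present; it equals the expected
    large-sample ROR for that pair.  ``coupling`` in [-1, 1] interpolates the
    query log between independent noise (0) and a fully shared latent trend
    (+/-1); its sign is the expected sign of the cross-domain Spearman rho.
    """

    seed: int = 0
    window: tuple[str, str] = DEFAULT_WINDOW
    n_reports_per_quarter: int = Field(default=400, gt=0)
    drugs: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_DRUGS))
    categories: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_CATEGORIES))
    enrichment: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {d: dict(c) for d, c in _DEFAULT_ENRICHMENT.items()}
    )
    latent_trend: Optional[list[float]] = None
    query_volume: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_QUERY_VOLUME))
    abuse_share: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_ABUSE_SHARE))
    coupling: float = Field(default=1.0, ge=-1.0, le=1.0)
    query_jitter_sigma: float = Field(default=0.1, ge=0.0)
    n_filler_drugs: int = Field(default=20, ge=1)
    filler_drug_p: float = Field(default=0.06, ge=0.0, le=1.0)
    n_filler_events: int = Field(default=30, ge=1)
    filler_event_p: float = Field(default=0.08, ge=0.0, le=1.0)

    @field_validator("drugs", "categories", "abuse_share")
    @classmethod
    def _probabilities(cls, v: dict[str, float]) -> dict[str, float]:
        for name, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} must be in [0, 1], got {p}")
        return v

    @field_validator("enrichment")
    @classmethod
    def _positive_odds(cls, v: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
        for d, cats in v.items():
            for c, m in cats.items():
                if m <= 0:
                    raise ValueError(f"enrichment for ({d!r}, {c!r}) must be > 0, got {m}")
        return v

    @model_validator(mode="after")
    def _check_window_and_trend(self) -> "SimulationConfig":
        n = len(quarter_range(*self.window))  # raises on malformed window
        if self.latent_trend is not None:
            if len(self.latent_trend) != n:
                raise ValueError(
                    f"latent_trend has {len(self.latent_trend)} values for a {n}-quarter window"
                )
            if min(self.latent_trend) <= 0:
                raise ValueError("latent_trend multipliers must be > 0")
        return self

    def trend(self) -> np.ndarray:
        """Per-quarter positive multiplier; default is a monotone ramp 0.5 -> 2.0."""
        n = len(quarter_range(*self.window))
        if self.latent_trend is not None:
            return np.asarray(self.latent_trend, dtype=float)
        return np.linspace(0.5, 2.0, n)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "window" in doc and isinstance(doc["window"], list):
            doc["window"] = tuple(doc["window"])
        return cls.model_validate(doc)


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expectations implied by a config alone."""

    expected_or: dict[tuple[str, str], float]
    expected_rho_sign: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "expected_or": {f"{d}|{c}": v for (d, c), v in self.expected_or.items()},
            "expected_rho_sign": dict(self.expected_rho_sign),
        }


def ground_truth(config: SimulationConfig) -> GroundTruth:
    """Expected odds ratios (= enrichment multipliers) and rho signs (= sign of coupling)."""
    expected_or = {
        (d, c): config.enrichment.get(d, {}).get(c, 1.0)
        for d in config.drugs
        for c in config.categories
    }
    sign = int(np.sign(config.coupling))
    return GroundTruth(expected_or, {d: sign for d in config.drugs})


def _group_rows(rows: np.ndarray, names: np.ndarray, n: int) -> list[frozenset]:
    """Group occurrence (row, name) pairs into one frozenset per row."""
    order = np.argsort(rows, kind="stable")
    rows = rows[order]
    names = names[order]
    counts = np.bincount(rows, minlength=n)
    sets: list[frozenset] = []
    pos = 0
    for cnt in counts:
        sets.append(frozenset(names[pos : pos + cnt]))
        pos += cnt
    return sets


def _category_objects(config: SimulationConfig) -> list[TermCategory]:
    _, vocab_cats, _ = load_default_vocab()
    by_name = {c.name: c for c in vocab_cats}
    out = []
    for name in config.categories:
        if name in by_name:
            out.append(by_name[name])
        else:  # user-defined category: a single PT equal to its name
            out.append(TermCategory(name, "secondary", (name,)))
    return out


def generate_reports(config: SimulationConfig) -> ReportStore:
    """Simulate a cleaned report store under the configured ground truth.

    Event PTs for a study category are drawn uniformly from that category's
    default PT list, so vocabulary mapping is exercised end to end; filler
    drugs and events populate the non-study cells of every 2x2 table.
    """
    rng = np.random.default_rng(config.seed)
    quarters = quarter_range(*config.window)
    trend = config.trend()
    drug_names = list(config.drugs)
    drug_p = np.array([config.drugs[d] for d in drug_names])
    categories = _category_objects(config)
    cat_p = np.array([config.categories[c.name] for c in categories])
    cat_pts = [np.array(c.pt_list, dtype=object) for c in categories]
    filler_drugs = np.array([f"filler drug {i:02d}" for i in range(config.n_filler_drugs)], dtype=object)
    filler_events = np.array([f"filler event {i:02d}" for i in range(config.n_filler_events)], dtype=object)
    all_drug_names = np.array(drug_names, dtype=object)

    n = config.n_reports_per_quarter
    reports: list[AdverseEventReport] = []
    for qi, q in enumerate(quarters):
        study_mat = rng.random((n, len(drug_names))) < drug_p
        filler_mat = rng.random((n, config.n_filler_drugs)) < config.filler_drug_p
        empty = ~(study_mat.any(axis=1) | filler_mat.any(axis=1))
        if empty.any():  # every report names at least one drug
            filler_mat[np.nonzero(empty)[0], rng.integers(0, config.n_filler_drugs, empty.sum())] = True

        base_odds = cat_p / (1.0 - cat_p) * trend[qi]
        odds = np.broadcast_to(base_odds, (n, len(categories))).copy()
        for di, dname in enumerate(drug_names):
            mults = np.array(
                [config.enrichment.get(dname, {}).get(c.name, 1.0) for c in categories]
            )
            present = study_mat[:, di]
            odds[present] *= mults
        cat_mat = rng.random((n, len(categories))) < odds / (1.0 + odds)
        filler_ev_mat = rng.random((n, config.n_filler_events)) < config.filler_event_p
        empty_ev = ~(cat_mat.any(axis=1) | filler_ev_mat.any(axis=1))
        if empty_ev.any():  # every report carries at least one event
            filler_ev_mat[np.nonzero(empty_ev)[0], rng.integers(0, config.n_filler_events, empty_ev.sum())] = True

        d_rows, d_cols = np.nonzero(study_mat)
        fd_rows, fd_cols = np.nonzero(filler_mat)
        drug_occ_rows = np.concatenate([d_rows, fd_rows])
        drug_occ_names = np.concatenate([all_drug_names[d_cols], filler_drugs[fd_cols]])
        drug_sets = _group_rows(drug_occ_rows, drug_occ_names, n)

        c_rows, c_cols = np.nonzero(cat_mat)
        pt_lens = np.array([len(p) for p in cat_pts])
        pick = rng.integers(0, pt_lens[c_cols]) if c_cols.size else np.array([], dtype=int)
        cat_names_occ = np.array(
            [cat_pts[c][k] for c, k in zip(c_cols, pick)], dtype=object
        )
        fe_rows, fe_cols = np.nonzero(filler_ev_mat)
        event_occ_rows = np.concatenate([c_rows, fe_rows])
        event_occ_names = np.concatenate([cat_names_occ, filler_events[fe_cols]])
        event_sets = _group_rows(event_occ_rows, event_occ_names, n)

        for i in range(n):
            reports.append(
                AdverseEventReport(
                    report_id=f"{q}-{i:06d}",
                    quarter=q,
                    drugs=drug_sets[i],
                    events=event_sets[i],
                )
            )
    return ReportStore(
        tuple(reports),
        window=config.window,
        known_drugs=frozenset(drug_names) | frozenset(filler_drugs.tolist()),
    )


def generate_query_log(config: SimulationConfig) -> list[QueryRecord]:
    """Simulate a quarterly query log for every configured drug.

    Emits per quarter and drug: the top (drug-name) query; abuse queries from
    the per-category templates with coupling-modulated volume; and two decoy
    queries — one matching the default blocklist collocation, one containing
    no abuse term — so downstream filtering has something to drop.
    """
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from the reports
    quarters = quarter_range(*config.window)
    trend = config.trend()
    log_t = np.log(trend)
    z = log_t - log_t.mean()
    scale = z.std()
    z_unit = z / scale if scale > 0 else np.zeros_like(z)
    sigma_shared = scale if scale > 0 else 0.3  # matched-variance independent component
    c = config.coupling
    records: list[QueryRecord] = []
    for drug, base in config.query_volume.items():
        share = config.abuse_share.get(drug, 0.0)
        eps = rng.standard_normal(len(quarters))
        log_mult = c * z_unit * sigma_shared + math.sqrt(max(0.0, 1 - c * c)) * sigma_shared * eps
        templates = [
            (cat, t.format(drug=drug))
            for cat in config.categories
            for t in _QUERY_TEMPLATES.get(cat, ("{drug} " + cat.replace("_", " "),))
        ]
        for qi, q in enumerate(quarters):
            top_vol = base * math.exp(rng.normal(0.0, 0.05))
            records.append(QueryRecord(query=drug, period=q, count=top_vol))
            for cat, text in templates:
                jitter = rng.normal(0.0, config.query_jitter_sigma)
                vol = (base * share / len(templates)) * math.exp(log_mult[qi] + jitter)
                records.append(QueryRecord(query=text, period=q, count=vol))
            records.append(
                QueryRecord(query=f"{drug} and high blood pressure", period=q, count=base * 0.03)
            )
            records.append(QueryRecord(query=f"{drug} dosage", period=q, count=base * 0.2))
    return records


# --- Named experiment scenarios -------------------------------------------
#
# These constructors pin down the study conditions for the package's
# calibration experiments; tests and demos share them so the conditions are
# defined in exactly one place.

def recovery_scenario(seed: int, enrichment: float = 3.0) -> SimulationConfig:
    """Parameter recovery: one drug-category pair, 200,000 reports.

    The latent trend is held constant: the crude odds ratio is noncollapsible
    across strata with differing baseline risk, so a varying trend would make
    the pooled ROR target a slightly attenuated value rather than the
    configured multiplier.  Recovery of the configured value is a property of
    the estimator, which this scenario isolates.
    """
    return SimulationConfig(
        seed=seed,
        window=("2007Q1", "2007Q4"),
        n_reports_per_quarter=50_000,
        latent_trend=[1.0] * 4,
        drugs={"drug a": 0.03},
        categories={"abuse": 0.03},
        enrichment={"drug a": {"abuse": enrichment}},
        query_volume={"drug a": 1.0},
        abuse_share={"drug a": 0.0},
        n_filler_drugs=8,
        filler_drug_p=0.1,
        n_filler_events=10,
        filler_event_p=0.15,
    )


def null_signal_scenario(seed: int) -> SimulationConfig:
    """Desk-scale null: the four study drugs with all enrichment at 1."""
    return SimulationConfig(
        seed=seed,
        enrichment={d: {c: 1.0 for c in _DEFAULT_CATEGORIES} for d in _DEFAULT_DRUGS},
    )


def coupled_scenario(seed: int, coupling: float = 1.0) -> SimulationConfig:
    """Cross-domain correlation: one drug with a strong shared monotone trend.

    Per-quarter co-report counts average a handful of reports (enough for the
    trend to dominate Poisson noise over the 54-quarter window) and the query
    log shares the same latent trend through the coupling parameter.
    """
    return SimulationConfig(
        seed=seed,
        coupling=coupling,
        n_reports_per_quarter=800,
        drugs={"drug a": 0.05},
        categories={"abuse": 0.05},
        enrichment={"drug a": {"abuse": 3.0}},
        query_volume={"drug a": 100_000.0},
        abuse_share={"drug a": 0.3},
        n_filler_drugs=8,
        filler_drug_p=0.1,
        n_filler_events=10,
        filler_event_p=0.15,
    )


def write_query_log_csv(records: list[QueryRecord], path: str | Path) -> None:
    """Query-log CSV: columns query, period, count, context_tag."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["query", "period", "count", "context_tag"])
        for r in records:
            writer.writerow([r.query, r.period, repr(r.count), r.context_tag])


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=2), encoding="utf-8")
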