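"""Drug-name and abuse-term dictionaries, and PT-to-category mapping.

The default vocabulary covers the four study drugs (the gabapentinoids
pregabalin and gabapentin, the positive control clonazepam, and the negative
control levetiracetam) and five drug-abuse-related event categories.  Each
category is an explicit list of MedDRA Preferred Terms (PTs); matching is
exact-string after case-folding and whitespace normalisation, with no
stemming or fuzzy matching.

The two SMQ-labelled categories (``drug_abuse_and_dependence``,
``drug_withdrawal``) ship with *placeholder* PT lists: the narrow-scope SMQ
membership is proprietary MedDRA content, so users holding a MedDRA licence
should override those lists via a vocabulary file.  For the other three
categories the PT membership is fully enumerated and authoritative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "DrugEntry",
    "TermCategory",
    "QueryTermSet",
    "load_default_vocab",
    "load_vocab",
    "map_pt",
    "normalize_term",
]


def normalize_term(s: str) -> str:
    """Case-fold and collapse internal/leading/trailing whitespace."""
    return " ".join(str(s).split()).casefold()


@dataclass(frozen=True)
class DrugEntry:
    """A study drug: lowercase generic name plus its brand-name aliases."""

    generic_name: str
    brand_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        generic = normalize_term(self.generic_name)
        brands = tuple(normalize_term(b) for b in self.brand_names)
        if not generic:
            raise ValueError("generic_name must be non-empty")
        if len(set(brands)) != len(brands):
            raise ValueError(f"duplicate brand names for {generic!r}")
        if generic in brands:
            raise ValueError(f"generic name {generic!r} repeated among brand names")
        object.__setattr__(self, "generic_name", generic)
        object.__setattr__(self, "brand_names", brands)

    @property
    def all_names(self) -> frozenset[str]:
        return frozenset((self.generic_name, *self.brand_names))


@dataclass(frozen=True)
class TermCategory:
    """A named set of event PTs; exactly one category per vocabulary is primary."""

    name: str
    scope: str  # "primary" | "secondary"
    pt_list: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.scope not in ("primary", "secondary"):
            raise ValueError(f"scope must be 'primary' or 'secondary', got {self.scope!r}")
        pts = tuple(normalize_term(p) for p in self.pt_list)
        if not pts:
            raise ValueError(f"category {self.name!r} has an empty PT list")
        object.__setattr__(self, "pt_list", pts)
        object.__setattr__(self, "_pt_set", frozenset(pts))

    @property
    def pt_set(self) -> frozenset[str]:
        return self._pt_set  # type: ignore[attr-defined]

    def matches(self, pt: str) -> bool:
        return normalize_term(pt) in self.pt_set


@dataclass(frozen=True)
class QueryTermSet:
    """Search-engine tokens paired with a term category of the same name."""

    name: str
    search_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        terms = tuple(normalize_term(t) for t in self.search_terms)
        if not terms:
            raise ValueError(f"query term set {self.name!r} is empty")
        object.__setattr__(self, "search_terms", terms)


def _validate(categories: list[TermCategory]) -> None:
    names = [c.name for c in categories]
    if len(set(names)) != len(names):
        raise ValueError("category names must be unique within a vocabulary")
    n_primary = sum(c.scope == "primary" for c in categories)
    if n_primary != 1:
        raise ValueError(f"exactly one category must have scope=primary, found {n_primary}")


def _build(doc: dict) -> tuple[list[DrugEntry], list[TermCategory], list[QueryTermSet]]:
    drugs = [
        DrugEntry(d["generic_name"], tuple(d.get("brand_names", ())))
        for d in doc.get("drugs", [])
    ]
    categories = [
        TermCategory(c["name"], c.get("scope", "secondary"), tuple(c["pt_list"]))
        for c in doc.get("categories", [])
    ]
    query_term_sets = [
        QueryTermSet(q["name"], tuple(q["search_terms"]))
        for q in doc.get("query_term_sets", [])
    ]
    _validate(categories)
    return drugs, categories, query_term_sets


def load_vocab(path: str | Path) -> tuple[list[DrugEntry], list[TermCategory], list[QueryTermSet]]:
    """Load a vocabulary from a JSON or YAML file.

    The file has top-level keys ``drugs`` (generic_name, brand_names),
    ``categories`` (name, scope, pt_list) and ``query_term_sets``
    (name, search_terms).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _build(doc)


def load_default_vocab() -> tuple[list[DrugEntry], list[TermCategory], list[QueryTermSet]]:
    """The packaged default vocabulary (four study drugs, five categories).

    The SMQ-based categories carry documented placeholder PT lists, not
    licensed MedDRA SMQ content; override them with :func:`load_vocab`.
    """
    ref = resources.files("vigitrends").joinpath("data/default_vocab.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _build(doc)


def map_pt(pt: str, categories: list[TermCategory]) -> set[str]:
    """Names of every category whose PT list contains *pt*.

    Matching case-folds and normalises whitespace; a PT may belong to several
    categories and all of them are returned.  Unknown PTs map to the empty set.
    """
    key = normalize_term(pt)
    return {c.name for c in categories if key in c.pt_set}
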