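"""Cross-domain monotonic association: Spearman rank correlation.

The report domain contributes a quarterly series (by default co-report
counts of the primary abuse category; optionally quarterly RORs) and the
search domain a quarterly cumulative abuse-SPS series.  After pairwise
removal of missing quarters, Spearman's rho is computed with average ranks
for ties, and the two-sided p-value from the t approximation
``t = rho * sqrt((n-2)/(1-rho**2))`` on n-2 degrees of freedom — standard at
the ~54-quarter sample sizes involved.  An exact permutation p-value is
available for very small n.

Rank correlation, not Pearson, because the two domains are expected to move
together monotonically, not at a constant rate — and no distributional
assumptions hold for either series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice, permutations
from typing import NamedTuple

import numpy as np
from scipy import stats

from .quarters import QuarterSeries

__all__ = [
    "CorrelationResult",
    "AlignedPair",
    "align_series",
    "spearman",
    "pvalue_from_rho",
    "exact_permutation_pvalue",
    "correlate_domains",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rho with paired sample size and two-sided p."""

    rho: float
    n: int
    p_two_sided: float


class AlignedPair(NamedTuple):
    x: np.ndarray
    y: np.ndarray
    quarters: tuple[str, ...]
    dropped_quarters: tuple[str, ...]


def align_series(x: QuarterSeries, y: QuarterSeries) -> AlignedPair:
    """Pairwise-complete values on the intersection of quarters, order kept.

    Quarters missing from either series, or carrying a missing value in
    either, are dropped from both and listed in ``dropped_quarters``.

    Raises
    ------
    ValueError
        If fewer than 3 complete pairs remain.
    """
    ymap = dict(zip(y.quarters, y.values))
    xs, ys, kept, dropped = [], [], [], []
    for q, xv in zip(x.quarters, x.values):
        yv = ymap.get(q, math.nan)
        if math.isfinite(xv) and math.isfinite(yv):
            xs.append(xv)
            ys.append(yv)
            kept.append(q)
        else:
            dropped.append(q)
    dropped.extend(q for q in y.quarters if q not in set(x.quarters))
    if len(xs) < 3:
        raise ValueError(
            f"insufficient overlap: only {len(xs)} complete quarter pairs (need >= 3)"
        )
    return AlignedPair(np.asarray(xs, float), np.asarray(ys, float), tuple(kept), tuple(dropped))


def spearman(x, y, method: str = "t") -> CorrelationResult:
    """Spearman rho of two paired value lists.

    *method* selects the p-value: ``"t"`` (default) uses the t approximation;
    ``"exact"`` enumerates all rank permutations (n <= 10 only).  Ties get
    average ranks.  |rho| = 1 yields the smallest positive float rather than
    an exact zero p.

    Raises
    ------
    ValueError
        On fewer than 3 pairs or zero variance in either rank vector.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D value lists")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("zero variance in a rank vector: rho undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    if method == "exact":
        p = exact_permutation_pvalue(x, y)
    elif method == "t":
        if abs(rho) >= 1.0:
            p = float(np.finfo(float).tiny)
        else:
            p = pvalue_from_rho(rho, n)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(rho=rho, n=n, p_two_sided=p)


def pvalue_from_rho(rho: float, n: int) -> float:
    """Two-sided p for a Spearman rho under the t approximation on n-2 df.

    Useful for checking printed (rho, p) pairs for consistency at a given
    sample size.  Requires |rho| < 1 and n >= 4.
    """
    if abs(rho) >= 1:
        raise ValueError(f"|rho| must be < 1 for the t approximation, got {rho}")
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def exact_permutation_pvalue(x, y, max_n: int = 10) -> float:
    """Exact two-sided permutation p for Spearman rho (small n only).

    Enumerates all n! assignments of y's ranks to x's ranks and counts
    |rho_perm| >= |rho_observed| (with a small numerical tolerance).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n > max_n:
        raise ValueError(f"exact permutation limited to n <= {max_n}, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    observed = abs(_rho_of_ranks(rx, ry))
    total = math.factorial(n)
    hits = 0
    perm_iter = permutations(ry)
    # chunked so n = 10 (3.6M permutations) stays within modest memory
    chunk_size = 40320
    while True:
        chunk = list(islice(perm_iter, chunk_size))
        if not chunk:
            break
        perms = np.array(chunk)
        pc = perms - perms.mean(axis=1, keepdims=True)
        rxc = rx - rx.mean()
        rhos = (pc @ rxc) / np.sqrt((pc * pc).sum(axis=1) * (rxc @ rxc))
        hits += int(np.sum(np.abs(rhos) >= observed - 1e-12))
    return hits / total


def correlate_domains(
    faers: QuarterSeries, sps: QuarterSeries, method: str = "t"
) -> tuple[CorrelationResult, tuple[str, ...]]:
    """Spearman correlation between a report-domain and a search-domain series.

    Returns the result plus the quarters dropped by pairwise-complete
    alignment, so the effective sample size is auditable.
    """
    pair = align_series(faers, sps)
    return spearman(pair.x, pair.y, method=method), pair.dropped_quarters
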