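"""Gene-set over-representation analysis.

For a query gene list of size n drawn from a universe of N genes, the overlap
k with a gene set of size K is tested against the hypergeometric upper tail
P(X >= k), X ~ Hypergeometric(N, K, n).  Benjamini-Hochberg FDR q-values are
computed across the whole tested collection: sets with zero overlap produce
no output row but still count toward the family size m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from scipy.special import gammaln, logsumexp

from .model import GeneSetCollection, PipelineError

__all__ = ["EnrichmentResult", "hypergeom_tail", "bh_fdr", "enrich",
           "DEFAULT_UNIVERSE_SIZE", "DEFAULT_COLLECTION_SIZE"]

#: Default gene-universe size for over-representation tests.
DEFAULT_UNIVERSE_SIZE = 45_956
#: Default multiple-testing family size for a KEGG-scale pathway collection.
DEFAULT_COLLECTION_SIZE = 186


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    set_size: int
    query_size: int
    overlap: int
    overlap_genes: tuple
    universe_size: int
    p_value: float
    q_value: float
    rank: int


def _log_hypergeom_pmf(j: int, N: int, K: int, n: int) -> float:
    return (
        gammaln(K + 1) - gammaln(j + 1) - gammaln(K - j + 1)
        + gammaln(N - K + 1) - gammaln(n - j + 1) - gammaln(N - K - n + j + 1)
        + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1)
    )


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    Log-space summation over the support; symmetric in (K, n).
    """
    if K > N or n > N or k < 0:
        raise PipelineError(f"inconsistent sizes: k={k}, K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise PipelineError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k == 0:
        return 1.0
    lo = max(k, K + n - N)
    hi = min(K, n)
    import numpy as np

    j = np.arange(lo, hi + 1)
    log_terms = _log_hypergeom_pmf(j, N, K, n)
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def bh_fdr(p_values: Sequence, m: Optional[int] = None) -> list:
    """Benjamini-Hochberg step-up q-values with family size m.

    ``m`` may exceed the number of supplied p-values when further tests were
    performed but their (non-significant) p-values are not listed; each
    supplied p-value keeps its rank among the supplied, sorted ascending.
    q_i = min over ranks j >= i of p_(j) * m / j, capped at 1.
    """
    p_values = list(p_values)
    ell = len(p_values)
    if m is None:
        m = ell
    if m < ell:
        raise PipelineError(f"family size m={m} smaller than list length {ell}")
    if any(not (0.0 <= p <= 1.0) for p in p_values):
        raise PipelineError("p-values must lie in [0, 1]")
    order = sorted(range(ell), key=lambda i: p_values[i])
    q_sorted = [0.0] * ell
    running = math.inf
    for rank_idx in range(ell - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p_values[i] * m / (rank_idx + 1))
        q_sorted[rank_idx] = min(running, 1.0)
    q = [0.0] * ell
    for rank_idx, i in enumerate(order):
        q[i] = q_sorted[rank_idx]
    return q


def enrich(query: Iterable, collection: GeneSetCollection,
           N: int = DEFAULT_UNIVERSE_SIZE) -> list:
    """Rank gene sets by hypergeometric over-representation of the query.

    Query genes are uppercase-normalized and deduplicated (a gene mutated
    several times counts once).  Sets with zero overlap are dropped from the
    output but remain in the BH family (m = collection.collection_size).
    """
    query_set = {str(g).upper() for g in query}
    if not query_set:
        raise PipelineError("query gene set is empty")
    if N < len(query_set):
        raise PipelineError(
            f"universe size N={N} smaller than query size {len(query_set)}"
        )
    hits = []
    for name, genes in collection.sets.items():
        overlap = sorted(query_set & genes)
        if not overlap:
            continue
        p = hypergeom_tail(len(overlap), len(genes), len(query_set), N)
        hits.append((name, genes, overlap, p))
    hits.sort(key=lambda h: (h[3], h[0]))
    qs = bh_fdr([h[3] for h in hits], m=collection.collection_size)
    return [
        EnrichmentResult(
            set_name=name,
            set_size=len(genes),
            query_size=len(query_set),
            overlap=len(overlap),
            overlap_genes=tuple(overlap),
            universe_size=N,
            p_value=p,
            q_value=q,
            rank=rank,
        )
        for rank, ((name, genes, overlap, p), q) in enumerate(zip(hits, qs), start=1)
    ]
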