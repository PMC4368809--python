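"""Hypergeometric over-representation of a gene list in named gene sets.

Given a query of n genes drawn from a universe of N genes, a set of K genes
containing k of the query is scored with the upper-tail hypergeometric
probability P(X >= k).  No multiple-testing correction is applied by default
(raw p-values are reported per set); Benjamini-Hochberg values are available
on request.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional

import numpy as np
from scipy.stats import hypergeom

from .genomic_io import GeneSetCollection

__all__ = ["EnrichmentResult", "hypergeom_upper_tail", "enrich_gene_sets"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    universe_size: int
    set_size: int
    query_size: int
    overlap: int
    expected: float
    p_value: float
    bh_fdr: Optional[float] = None


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def enrich_gene_sets(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    bh: bool = False,
) -> List[EnrichmentResult]:
    """Score every set in the collection against the query; sorted by (p, name).

    Query genes outside the universe are dropped (with a logged count) so the
    hypergeometric geometry stays consistent.
    """
    if not collection.universe:
        raise ValueError("empty gene universe")
    query = set(query_genes)
    dropped = query - collection.universe
    if dropped:
        logger.info("dropping %d query genes outside the universe", len(dropped))
    query &= collection.universe
    N, n = len(collection.universe), len(query)
    results: List[EnrichmentResult] = []
    for name, genes in collection.sets.items():
        K = len(genes)
        k = len(query & genes)
        results.append(
            EnrichmentResult(
                set_name=name,
                universe_size=N,
                set_size=K,
                query_size=n,
                overlap=k,
                expected=n * K / N,
                p_value=hypergeom_upper_tail(N, K, n, k),
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    if bh and results:
        pvals = np.array([r.p_value for r in results])
        m = len(pvals)
        ranked = pvals * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        results = [
            EnrichmentResult(
                r.set_name, r.universe_size, r.set_size, r.query_size, r.overlap,
                r.expected, r.p_value, bh_fdr=float(min(1.0, q)),
            )
            for r, q in zip(results, adj)
        ]
    return results
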