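"""Gene-set over-representation analysis.

For a query of n genes drawn from a universe of G genes, a term with K
members in the universe and k members in the query is scored with the
one-sided hypergeometric upper tail P(X >= k); Benjamini-Hochberg FDR
is applied across the tested terms of one collection.  The default
universe is the set of annotated, non-pseudogene genes on the array.
Only over-representation is tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io_formats import GeneSetCollection

__all__ = ["EnrichmentResult", "enrich"]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    term_id: str
    overlap_count: int        # k
    term_size: int            # K (within the universe)
    query_size: int           # n (within the universe)
    universe_size: int        # G
    p_value: float            # P(X >= k), exact
    fdr: float                # BH across tested terms
    neg_log10_p: float


def enrich(query_genes: Iterable[str], collection: GeneSetCollection,
           universe: Iterable[str]) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the query.

    Query genes outside the universe are dropped with a warning; term
    members are intersected with the universe before sizing.  Results
    are sorted by p-value, ties by term id.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    query = set(query_genes)
    dropped = query - universe
    if dropped:
        logger.warning("dropping %d query gene(s) outside the universe",
                       len(dropped))
    query &= universe
    if not query:
        raise ValidationError("query is empty after intersecting the universe")
    G, n = len(universe), len(query)
    results = []
    pvals = []
    for term_id, _desc, members in collection:
        in_universe = set(members) & universe
        K = len(in_universe)
        if K == 0:
            continue
        k = len(in_universe & query)
        p = float(hypergeom.sf(k - 1, G, K, n))
        pvals.append(p)
        results.append(EnrichmentResult(
            term_id=term_id, overlap_count=k, term_size=K, query_size=n,
            universe_size=G, p_value=p, fdr=np.nan,
            neg_log10_p=float(-np.log10(p)) if p > 0 else np.inf))
    if results:
        fdr = multipletests(pvals, method="fdr_bh")[1]
        for r, f in zip(results, fdr):
            r.fdr = float(f)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
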