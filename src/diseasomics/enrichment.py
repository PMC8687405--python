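"""Over-representation analysis and gene-disease association testing.

The statistic is the upper-tail hypergeometric probability: with a universe
of N genes of which K belong to a term, the chance that a query of n genes
overlaps the term in at least k genes, P(X >= k) for
X ~ Hypergeometric(N, K, n) — the one-sided Fisher convention used by
enrichment web services.  p-values are Benjamini-Hochberg adjusted within
one library (or within one batch of disease-association queries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from diseasomics.dataio import GeneSetLibrary
from diseasomics.deg import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    description: str
    k: int  # overlap size
    K: int  # term size within universe
    n: int  # query size within universe
    N: int  # universe size
    overlap_genes: frozenset[str]
    p: float
    p_adj: float


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeometric(N, K, n).

    ``k`` successes drawn, ``K`` marked in the population, ``n`` drawn,
    ``N`` population size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N (got k={k}, K={K}, n={n}, N={N})")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n) (got k={k}, K={K}, n={n})")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _clean(genes) -> frozenset[str]:
    return frozenset(str(g).upper() for g in genes)


def enrich(
    query,
    lib: GeneSetLibrary,
    universe=None,
) -> list[EnrichmentResult]:
    """Over-representation of a gene set against every term of a library.

    The universe defaults to the library's own universe.  Every term of the
    library is tested (BH adjustment spans them all); terms with zero overlap
    are omitted from the returned list, which is sorted by p_adj, then p,
    then term id.
    """
    raw_query = _clean(query)
    if not raw_query:
        raise ValueError("empty query gene set")
    uni = _clean(universe) if universe is not None else frozenset(lib.universe)
    if not uni:
        raise ValueError("empty universe")
    q = raw_query & uni
    if not q:
        raise ValueError(
            f"query has no overlap with the universe ({len(raw_query)} query genes, "
            f"{len(uni)} universe genes)"
        )
    N, n = len(uni), len(q)

    terms = sorted(lib.sets)
    records = []
    for term in terms:
        desc, genes = lib.sets[term]
        tg = genes & uni
        K = len(tg)
        overlap = q & tg
        k = len(overlap)
        p = hypergeom_upper(k, K, n, N) if K else 1.0
        records.append((term, desc, k, K, overlap, p))

    p_adj = benjamini_hochberg([r[5] for r in records])
    results = [
        EnrichmentResult(term, desc, k, K, n, N, frozenset(overlap), p, float(pa))
        for (term, desc, k, K, overlap, p), pa in zip(records, p_adj)
        if k >= 1
    ]
    results.sort(key=lambda r: (r.p_adj, r.p, r.term_id))
    return results


def gene_disease_association(
    degs,
    disease_genes,
    universe,
) -> EnrichmentResult:
    """Hypergeometric overlap of a DEG set with a known disease gene list.

    Disease genes outside the universe are dropped (logged).  For a batch of
    risk factors use :func:`associate_batch`, which BH-adjusts across the
    batch; a single call reports p_adj = p.
    """
    uni = _clean(universe)
    if not uni:
        raise ValueError("empty universe")
    dg = _clean(disease_genes)
    outside = dg - uni
    if outside:
        logger.info("%d disease gene(s) outside the universe dropped", len(outside))
    dg &= uni
    q = _clean(degs) & uni
    overlap = q & dg
    p = hypergeom_upper(len(overlap), len(dg), len(q), len(uni))
    return EnrichmentResult(
        term_id="disease_genes",
        description="gene-disease association",
        k=len(overlap),
        K=len(dg),
        n=len(q),
        N=len(uni),
        overlap_genes=frozenset(overlap),
        p=p,
        p_adj=p,
    )


def associate_batch(
    queries: dict[str, frozenset[str]],
    disease_genes,
    universe,
) -> list[EnrichmentResult]:
    """Gene-disease association for several risk factors, BH across the batch."""
    if not queries:
        raise ValueError("no queries")
    names = sorted(queries)
    singles = [gene_disease_association(queries[name], disease_genes, universe) for name in names]
    p_adj = benjamini_hochberg([r.p for r in singles])
    return [
        EnrichmentResult(
            term_id=name,
            description="gene-disease association",
            k=r.k,
            K=r.K,
            n=r.n,
            N=r.N,
            overlap_genes=r.overlap_genes,
            p=r.p,
            p_adj=float(pa),
        )
        for name, r, pa in zip(names, singles, p_adj)
    ]


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "description": [r.description for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "overlap_genes": [",".join(sorted(r.overlap_genes)) for r in results],
        }
    )
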