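"""GO term-for-term enrichment with ancestor propagation.

Gene-to-term assignments are closed under is_a/part_of ancestry (the
true-path rule), each term with at least one study and one population
gene is tested with a hypergeometric upper tail, and Benjamini-Hochberg
correction is applied across the terms actually tested in the run. The
background is the set of all GO-annotated genes; study genes without
annotations are dropped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import OntologyTerm

log = logging.getLogger(__name__)


@dataclass
class GeneTermMap:
    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    study_count: int      # k
    study_size: int       # n
    population_count: int  # K
    population_size: int   # N
    p_raw: float
    p_adjusted: float
    enriched: bool


def propagate(direct: dict[str, set[str]], ontology: list[OntologyTerm]) -> GeneTermMap:
    """Close each gene's term set under is_a/part_of ancestry.

    Genes with no terms are absent from the propagated map; a diamond in
    the DAG contributes each ancestor once (set semantics).
    """
    parents: dict[str, list[str]] = {}
    for term in ontology:
        parents[term.term_id] = [p for p, rel in term.parents if rel in ("is_a", "part_of")]

    ancestors_cache: dict[str, frozenset[str]] = {}

    def ancestors(term_id: str) -> frozenset[str]:
        cached = ancestors_cache.get(term_id)
        if cached is not None:
            return cached
        acc: set[str] = {term_id}
        for p in parents.get(term_id, []):
            acc |= ancestors(p)
        result = frozenset(acc)
        ancestors_cache[term_id] = result
        return result

    propagated: dict[str, set[str]] = {}
    for gene, terms in direct.items():
        if not terms:
            continue
        full: set[str] = set()
        for t in terms:
            full |= ancestors(t)
        propagated[gene] = full
    return GeneTermMap(direct=direct, propagated=propagated)


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    if not pvals:
        raise ValueError("need at least one p-value")
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    return [float(p) for p in adj]


def enrich(
    study_genes: set[str] | list[str],
    gene_term_map: GeneTermMap,
    alpha: float = 0.05,
) -> tuple[list[EnrichmentResult], int]:
    """Term-for-term enrichment of a study gene set against the
    GO-annotated background.

    Returns results sorted by adjusted p (ties by term id) and the
    number of study genes dropped for lacking GO annotations.
    """
    prop = gene_term_map.propagated
    background = set(prop)
    study = set(study_genes) & background
    n_dropped = len(set(study_genes)) - len(study)
    if n_dropped:
        log.info("%d study genes without GO annotations dropped", n_dropped)
    N = len(background)
    n = len(study)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        in_study = gene in study
        for t in prop[gene]:
            term_pop[t] = term_pop.get(t, 0) + 1
            if in_study:
                term_study[t] = term_study.get(t, 0) + 1
    tested = sorted(t for t, k in term_study.items() if k >= 1)
    if not tested:
        return [], n_dropped
    praw = [hypergeom_upper(term_study[t], n, term_pop[t], N) for t in tested]
    padj = bh_adjust(praw)
    results = [
        EnrichmentResult(
            term_id=t,
            term_name="",
            study_count=term_study[t],
            study_size=n,
            population_count=term_pop[t],
            population_size=N,
            p_raw=p,
            p_adjusted=q,
            enriched=q <= alpha,
        )
        for t, p, q in zip(tested, praw, padj)
    ]
    results.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))
    return results, n_dropped


def attach_term_names(results: list[EnrichmentResult], ontology: list[OntologyTerm]) -> None:
    names = {t.term_id: t.name for t in ontology}
    for r in results:
        r.term_name = names.get(r.term_id, "")


def genes_in_regions(gene_models, regions) -> set[str]:
    """Genes whose annotation span intersects any of the given intervals
    (the collapsed-region study-set rule)."""
    out = set()
    for gene in gene_models:
        for iv in regions:
            if gene.span.overlaps(iv):
                out.add(gene.gene_id)
                break
    return out
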