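"""Gene-set enrichment of differentially methylated genes (DMGs).

Per term, over-representation is scored with the hypergeometric upper tail:
with N background genes, K of them in the term, and a query of n DMGs of
which k fall in the term, p = P[X >= k], X ~ Hypergeom(N, K, n). Fold
enrichment is (k/n)/(K/N). Reported pathways follow the study's filters:
at least ``min_count`` DMGs in the term and fold enrichment >= ``min_fold``.

Annotation clusters approximate DAVID-style functional clustering: terms are
linked when Cohen's kappa of their query-membership vectors reaches a
threshold, clusters are the connected components, and the cluster enrichment
score is -log10 of the geometric mean of member p-values. Reported clusters
need >= 2 terms and a strict majority of members with q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .mnm import bh_fdr


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    dmg_count: int           # k
    term_size: int           # K (within background)
    query_size: int          # n
    background_size: int     # N
    fold_enrichment: float
    p_value: float
    q_value: float
    genes: tuple[str, ...]   # query genes in the term


@dataclass(frozen=True)
class TermCluster:
    terms: tuple[EnrichmentResult, ...]
    enrichment_score: float  # -log10 geometric mean of member p-values


def enrich_terms(
    query_genes,
    gene_sets,
    background_genes,
    min_count: int = 2,
    min_fold: float = 1.5,
    apply_filters: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment with BH correction across all tested
    terms; the returned list is filtered (k >= min_count, fold >= min_fold
    unless ``apply_filters`` is off) and sorted by p-value.

    ``gene_sets`` maps term_id -> (term_name, genes) or term_id -> genes.
    Term membership is intersected with the background before testing.
    """
    background = set(background_genes)
    query = set(query_genes)
    stray = sorted(query - background)
    if stray:
        raise ValueError(f"query genes absent from background: {stray}")
    n = len(query)
    N = len(background)

    tested: list[tuple[str, str, set, int]] = []
    for term_id, value in gene_sets.items():
        if isinstance(value, tuple) and len(value) == 2 and not isinstance(value, str):
            name, members = value
        else:
            name, members = term_id, value
        members = set(members) & background
        if not members:
            continue
        tested.append((term_id, name, members, len(members)))
    if not tested or n == 0:
        return []

    p_values = []
    results = []
    for term_id, name, members, K in tested:
        hits = tuple(sorted(query & members))
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(max(p, np.finfo(float).tiny), 1.0)
        fold = (k / n) / (K / N)
        p_values.append(p)
        results.append(
            EnrichmentResult(term_id, name, k, K, n, N, fold, p, np.nan, hits)
        )
    q_values = bh_fdr(p_values)
    results = [
        EnrichmentResult(
            r.term_id, r.term_name, r.dmg_count, r.term_size, r.query_size,
            r.background_size, r.fold_enrichment, r.p_value, float(q), r.genes,
        )
        for r, q in zip(results, q_values)
    ]
    if apply_filters:
        results = [
            r for r in results
            if r.dmg_count >= min_count and r.fold_enrichment >= min_fold
        ]
    return sorted(results, key=lambda r: (r.p_value, r.term_id))


def binary_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa for two binary membership vectors.

    Degenerate case: identical constant vectors agree perfectly but have no
    chance-corrected information; returned as 1.0 (they co-cluster).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("membership vectors differ in length")
    n = a.size
    po = float(np.mean(a == b))
    pa1, pb1 = float(a.mean()), float(b.mean())
    pe = pa1 * pb1 + (1.0 - pa1) * (1.0 - pb1)
    if pe >= 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def cluster_terms(
    results,
    query_genes,
    kappa_threshold: float = 0.5,
    alpha: float = 0.05,
) -> list[TermCluster]:
    """Group enriched terms into annotation clusters by membership kappa.

    Terms are nodes; an edge joins two terms whose query-gene membership
    vectors have kappa >= threshold; clusters are connected components.
    Clusters with < 2 terms, or without a strict majority of members at
    q < alpha, are dropped. Output sorted by descending enrichment score.
    """
    results = list(results)
    if not results:
        return []
    universe = sorted(set(query_genes))
    index = {g: i for i, g in enumerate(universe)}
    vectors = np.zeros((len(results), len(universe)), dtype=bool)
    for i, r in enumerate(results):
        for g in r.genes:
            vectors[i, index[g]] = True

    parent = list(range(len(results)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(results)):
        for j in range(i + 1, len(results)):
            if binary_kappa(vectors[i], vectors[j]) >= kappa_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    groups: dict[int, list[EnrichmentResult]] = {}
    for i, r in enumerate(results):
        groups.setdefault(find(i), []).append(r)

    clusters = []
    for members in groups.values():
        if len(members) < 2:
            continue
        n_sig = sum(1 for r in members if r.q_value < alpha)
        if n_sig * 2 <= len(members):
            continue
        score = float(-np.mean(np.log10([r.p_value for r in members])))
        ordered = tuple(sorted(members, key=lambda r: (r.p_value, r.term_id)))
        clusters.append(TermCluster(ordered, score))
    return sorted(clusters, key=lambda c: -c.enrichment_score)
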