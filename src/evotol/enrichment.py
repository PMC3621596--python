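"""Hypergeometric (one-sided Fisher) GO-term over-representation with FDR.

For each term annotated in the population, the study set's annotation count
is tested against the hypergeometric null: with N population genes of which
K carry the term, and a study set of n genes of which k carry it,

    p = sum_{i >= k} C(K, i) C(N - K, n - i) / C(N, n)

(the upper tail, equal to the one-sided Fisher exact test on the 2x2
table).  Annotations are first propagated up the is_a hierarchy so a gene
annotated to a term counts for every ancestor.  Multiplicity is controlled
with Benjamini-Hochberg step-up q-values; a term is flagged enriched when
q < alpha (default 0.05).

The background population defaults to the set of strains actually screened
(the deletion collection), which matches the sampling design of the screen
better than the whole genome would.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "GOAnnotationTable",
    "EnrichmentResult",
    "hypergeom_tail",
    "bh_fdr",
    "enrich",
]


def _log_comb(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), in log space.

    k: study genes with the term; K: population genes with the term;
    n: study size; N: population size.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible margins: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"impossible table: k={k} with K={K}, n={n}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


class GOAnnotationTable:
    """Gene->term annotations plus the is_a term hierarchy.

    ``annotations``: mapping gene -> set of term ids (or a two-column
    gene/term DataFrame); ``edges``: iterable of (child, parent) is_a pairs
    (or a child/parent DataFrame); ``names``: optional term id -> name map.
    The hierarchy must be acyclic and every annotated term must appear in it
    (terms with no edges are allowed as isolated hierarchy nodes).
    """

    def __init__(self, annotations, edges=(), names: dict | None = None):
        if isinstance(annotations, pd.DataFrame):
            grouped = annotations.groupby("gene")["term"].agg(set)
            self.gene_terms = {g: set(ts) for g, ts in grouped.items()}
        else:
            self.gene_terms = {g: set(ts) for g, ts in dict(annotations).items()}
        if isinstance(edges, pd.DataFrame):
            edge_list = list(edges[["child", "parent"]].itertuples(index=False, name=None))
        else:
            edge_list = [tuple(e) for e in edges]
        self.graph = nx.DiGraph(edge_list)  # child -> parent
        for terms in self.gene_terms.values():
            self.graph.add_nodes_from(terms)
        self.names = dict(names or {})
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValueError(f"term hierarchy contains a cycle: {cycle}")

    def ancestors(self, term: str) -> set:
        """Reflexive-transitive is_a closure of one term."""
        return {term} | nx.descendants(self.graph, term)  # edges point child->parent

    def propagate(self) -> "GOAnnotationTable":
        """Annotate every gene to all ancestors of its terms; idempotent."""
        closure: dict[str, set] = {}
        propagated = {}
        for gene, terms in self.gene_terms.items():
            full: set = set()
            for t in terms:
                if t not in closure:
                    closure[t] = self.ancestors(t)
                full |= closure[t]
            propagated[gene] = full
        out = GOAnnotationTable.__new__(GOAnnotationTable)
        out.gene_terms = propagated
        out.graph = self.graph
        out.names = self.names
        return out

    def term_counts(self, genes) -> dict:
        counts: dict[str, int] = {}
        for g in genes:
            for t in self.gene_terms.get(g, ()):
                counts[t] = counts.get(t, 0) + 1
        return counts


def propagate_annotations(table: GOAnnotationTable) -> GOAnnotationTable:
    return table.propagate()


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p: float
    q: float
    enriched: bool


def enrich(
    study_set,
    population,
    table: GOAnnotationTable,
    alpha: float = 0.05,
    *,
    min_population_count: int = 2,
    propagate: bool = True,
) -> list[EnrichmentResult]:
    """Test every population-annotated term for over-representation in the study set.

    Terms annotating fewer than ``min_population_count`` population genes
    are skipped as degenerate.  Results are sorted by (q, p, term) and
    flagged enriched when q < alpha.
    """
    study = set(study_set)
    pop = set(population)
    missing = study - pop
    if missing:
        raise ValueError(f"study genes absent from population: {sorted(missing)}")
    tab = table.propagate() if propagate else table
    pop_counts = tab.term_counts(pop)
    study_counts = tab.term_counts(study)
    n, N = len(study), len(pop)

    terms = sorted(t for t, K in pop_counts.items() if K >= min_population_count)
    pvals = np.array(
        [hypergeom_tail(study_counts.get(t, 0), pop_counts[t], n, N) for t in terms]
    )
    qvals = bh_fdr(pvals)
    results = [
        EnrichmentResult(
            term=t,
            name=tab.names.get(t, ""),
            k=study_counts.get(t, 0),
            K=pop_counts[t],
            n=n,
            N=N,
            p=float(p),
            q=float(q),
            enriched=bool(q < alpha),
        )
        for t, p, q in zip(terms, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.q, r.p, r.term))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "name": r.name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
                "enriched": r.enriched,
            }
            for r in results
        ]
    )
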