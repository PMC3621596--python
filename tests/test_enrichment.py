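"""Hypergeometric tail, BH FDR, hierarchy propagation, end-to-end enrichment."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats
from statsmodels.stats.multitest import multipletests

from evotol import GOAnnotationTable, bh_fdr, enrich, hypergeom_tail
from evotol.fixtures import load_fixture
from evotol.synthetic import generate_go_annotations


def brute_force_tail(k, K, n, N):
    denom = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / denom


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k,K,n,N,expected",
        [
            (0, 5, 5, 20, 1.0),
            (2, 2, 2, 10, 1 / 45),            # C(2,2)C(8,0)/C(10,2)
            (3, 5, 5, 20, 1126 / 15504),       # brute-force sum over i = 3,4,5
        ],
    )
    def test_worked_examples(self, k, K, n, N, expected):
        assert hypergeom_tail(k, K, n, N) == pytest.approx(expected, rel=1e-12)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            N = int(rng.integers(2, 60))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_tail(k, K, n, N) == pytest.approx(
                brute_force_tail(k, K, n, N), rel=1e-10, abs=1e-300
            )

    def test_matches_scipy_survival_function(self):
        # independent route: scipy's hypergeometric sf at k-1
        for k, K, n, N in [(5, 40, 35, 5154), (9, 40, 35, 5154), (1, 3, 10, 50)]:
            assert hypergeom_tail(k, K, n, N) == pytest.approx(
                scipy.stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9
            )

    def test_equals_one_sided_fisher_exact(self):
        table = [[4, 31], [36, 5083]]  # k, n-k / K-k, N-K-n+k
        _, fisher_p = scipy.stats.fisher_exact(table, alternative="greater")
        assert hypergeom_tail(4, 40, 35, 5154) == pytest.approx(fisher_p, rel=1e-9)

    def test_impossible_tables_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_tail(1, 11, 5, 10)


class TestBhFdr:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.05], [0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([1.0, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_step_up(self, pvals, expected):
        np.testing.assert_allclose(bh_fdr(pvals), expected)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_ref, rtol=1e-12)

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def naive_dfs_ancestors(edges, term):
    """Independent closure oracle: iterative DFS over child->parent edges."""
    adj = {}
    for child, parent in edges:
        adj.setdefault(child, []).append(parent)
    seen, stack = {term}, [term]
    while stack:
        for p in adj.get(stack.pop(), []):
            if p not in seen:
                seen.add(p)
                stack.append(p)
    return seen


class TestPropagation:
    def test_single_edge_closure(self):
        t = GOAnnotationTable({"g": {"child"}}, [("child", "parent")]).propagate()
        assert t.gene_terms["g"] == {"child", "parent"}

    def test_idempotent(self):
        t = GOAnnotationTable(
            {"g": {"a"}, "h": {"b"}}, [("a", "b"), ("b", "root")]
        ).propagate()
        again = t.propagate()
        assert again.gene_terms == t.gene_terms

    def test_diamond_counted_once(self):
        edges = [("leaf", "l"), ("leaf", "r"), ("l", "root"), ("r", "root")]
        t = GOAnnotationTable({"g": {"leaf"}}, edges).propagate()
        assert t.gene_terms["g"] == naive_dfs_ancestors(edges, "leaf")

    def test_ancestor_counts_monotone(self):
        rng = np.random.default_rng(3)
        # random DAG: edge i -> j only for i < j keeps it acyclic
        terms = [f"t{i}" for i in range(15)]
        edges = [
            (terms[i], terms[j])
            for i in range(15)
            for j in range(i + 1, 15)
            if rng.random() < 0.2
        ]
        genes = {f"g{i}": {str(rng.choice(terms))} for i in range(40)}
        table = GOAnnotationTable(genes, edges).propagate()
        counts = table.term_counts(genes)
        g = nx.DiGraph(edges)
        for child, parent in g.edges:
            assert counts.get(parent, 0) >= counts.get(child, 0)

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            GOAnnotationTable({"g": {"a"}}, [("a", "b"), ("b", "a")])


class TestEnrich:
    def test_study_equals_population_nothing_enriched(self):
        genes = {f"g{i}": {"t1" if i < 5 else "t2"} for i in range(20)}
        table = GOAnnotationTable(genes, [("t1", "root"), ("t2", "root")])
        results = enrich(list(genes), list(genes), table)
        assert all(r.p == 1.0 for r in results)
        assert not any(r.enriched for r in results)

    def test_planted_term_flagged(self):
        population = [f"g{i}" for i in range(5154)]
        study = population[:35]
        # planted: 40 population genes carry the term, 9 of them in the study
        members = study[:9] + population[100:131]
        genes = {g: {"planted"} for g in members}
        table = GOAnnotationTable(genes, [("planted", "root")])
        results = enrich(study, population, table)
        planted = next(r for r in results if r.term == "planted")
        assert planted.k == 9 and planted.K == 40
        assert planted.p == pytest.approx(brute_force_tail(9, 40, 35, 5154), rel=1e-9)
        assert planted.enriched

    def test_study_gene_missing_from_population_is_reported(self):
        table = GOAnnotationTable({"a": {"t"}}, [("t", "root")])
        with pytest.raises(ValueError, match="ghost"):
            enrich(["a", "ghost"], ["a"], table)

    def test_null_pvalues_are_valid(self):
        # random study sets from an unstructured population: fraction of
        # terms with p < alpha must not exceed alpha beyond MC error
        rng = np.random.default_rng(4)
        population = [f"g{i}" for i in range(300)]
        ann, edges, names = generate_go_annotations(
            population, planted={}, n_background_terms=60,
            term_size_range=(10, 60), seed=5,
        )
        table = GOAnnotationTable(ann, edges, names)
        alpha = 0.05
        hits = total = 0
        for _ in range(40):
            study = rng.choice(population, size=30, replace=False)
            for r in enrich(study, population, table, propagate=True):
                total += 1
                hits += r.p < alpha
        rate = hits / total
        mc_err = math.sqrt(alpha * (1 - alpha) / total)
        assert rate <= alpha + 3 * mc_err

    def test_table1_clusters_enrich_against_synthetic_background(self):
        table1 = load_fixture("table1_genes")
        study = list(table1["gene"])
        population = study + [f"Y{i:05d}" for i in range(5154 - len(study))]
        planted = {
            "GO:9000101": ("proteasome complex",
                           table1.loc[table1["category"] == "UPS", "gene"]),
            "GO:9000102": ("multivesicular body",
                           table1.loc[table1["category"] == "MVB", "gene"]),
        }
        ann, edges, names = generate_go_annotations(population, planted, seed=6)
        table = GOAnnotationTable(ann, edges, names)
        results = {r.term: r for r in enrich(study, population, table, alpha=0.05)}
        assert results["GO:9000101"].enriched
        assert results["GO:9000102"].enriched
        # their shared parent picks up both clusters through propagation
        assert results["GO:9000001"].k >= 9
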