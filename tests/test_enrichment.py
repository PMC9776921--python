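import math

import numpy as np
import pytest

from mdconet import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCatalog,
    SampleLabels,
    default_config,
    gsea_enrichment_score,
    gsea_permutation_p,
    ora_hypergeometric,
    pathway_membership_counts,
    rank_genes,
    simulate_gene_sets,
    simulate_paired_cohorts,
)
from mdconet.enrichment import RankedList
from mdconet.io import ValidationError


def _es_oracle(genes, metric, members, weight):
    """Position-by-position running-sum walk, independent of the vectorised path."""
    members = set(members)
    hit_mass = [abs(m) ** weight if g in members else 0.0 for g, m in zip(genes, metric)]
    total_hit = sum(hit_mass)
    n_miss = sum(1 for g in genes if g not in members)
    running = []
    acc = 0.0
    for g, hm in zip(genes, hit_mass):
        if g in members:
            acc += hm / total_hit
        else:
            acc -= 1.0 / n_miss
        running.append(acc)
    extreme = 0.0
    for value in running:
        if abs(value) > abs(extreme):
            extreme = value
    return extreme, running


def _hypergeom_tail_oracle(N, K, n, k):
    """P[X >= k] by summing the pmf written out with binomial coefficients."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    return total


class TestRankGenes:
    def _matrix(self, values):
        values = np.asarray(values, dtype=float)
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        mat = ExpressionMatrix(
            [f"G{i}" for i in range(values.shape[0])], samples, values
        )
        labels = SampleLabels({s: s[0] for s in samples})
        return mat, labels

    def test_direct_formula(self):
        # mu_A = 1, mu_B = 0, sd_A = sd_B = 0.5 -> metric 1.0
        a = np.array([0.5, 1.0, 1.5])
        b = np.array([-0.5, 0.0, 0.5])
        mat, labels = self._matrix(np.vstack([np.r_[a, b], np.r_[b, a]]))
        ranked = rank_genes(mat, labels)
        sd = np.std(a, ddof=1)
        expected = 1.0 / (2 * sd)
        idx = ranked.genes.index("G0")
        assert ranked.metric[idx] == pytest.approx(expected)

    def test_label_swap_negates_and_reverses(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(20, 6)) + np.linspace(0, 2, 20)[:, None] * np.r_[
            np.ones(3), np.zeros(3)
        ]
        mat, labels = self._matrix(values)
        swapped = SampleLabels(
            {s: ("B" if c == "A" else "A") for s, c in labels.mapping.items()}
        )
        r1 = rank_genes(mat, labels)
        r2 = rank_genes(mat, swapped)
        by_gene1 = dict(zip(r1.genes, r1.metric))
        by_gene2 = dict(zip(r2.genes, r2.metric))
        for g in by_gene1:
            assert by_gene1[g] == pytest.approx(-by_gene2[g])
        assert r1.genes == r2.genes[::-1] or set(r1.genes) == set(r2.genes)

    def test_constant_gene_gets_zero_metric(self):
        values = np.vstack([np.zeros(6), np.r_[np.ones(3), np.zeros(3)]])
        mat, labels = self._matrix(values)
        ranked = rank_genes(mat, labels)
        assert ranked.metric[ranked.genes.index("G0")] == 0.0


class TestEnrichmentScore:
    def test_all_hits_precede_misses_gives_unit_score(self):
        ranked = RankedList([f"g{i}" for i in range(10)], np.arange(10, 0, -1.0))
        es, _ = gsea_enrichment_score(ranked, {"g0", "g1"}, weight=0.0)
        assert es == pytest.approx(1.0)

    def test_set_equals_universe_gives_unit_score(self):
        ranked = RankedList(["a", "b", "c"], np.array([3.0, 2.0, 1.0]))
        es, running = gsea_enrichment_score(ranked, {"a", "b", "c"})
        assert es == pytest.approx(1.0)
        assert running[-1] == pytest.approx(1.0)

    def test_no_member_raises(self):
        ranked = RankedList(["a", "b"], np.array([2.0, 1.0]))
        with pytest.raises(ValidationError):
            gsea_enrichment_score(ranked, {"zz"})

    def test_matches_walk_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(500):
            n = int(rng.integers(5, 50))
            genes = [f"g{i}" for i in range(n)]
            metric = np.sort(rng.normal(size=n))[::-1]
            size = int(rng.integers(1, n))
            members = list(rng.choice(genes, size=size, replace=False))
            weight = float(rng.choice([0.0, 1.0, 1.5]))
            es, running = gsea_enrichment_score(
                RankedList(genes, metric), members, weight=weight
            )
            es_oracle, running_oracle = _es_oracle(genes, metric, members, weight)
            assert np.allclose(running, running_oracle, atol=1e-12)
            assert es == pytest.approx(es_oracle, abs=1e-12)


class TestPermutationP:
    def test_top_set_of_strong_ranking_attains_the_floor(self):
        rng = np.random.default_rng(2)
        metric = np.sort(rng.normal(size=200))[::-1] + np.linspace(5, 0, 200)
        ranked = RankedList([f"g{i}" for i in range(200)], metric)
        res = gsea_permutation_p(ranked, [f"g{i}" for i in range(10)], n_perm=500, seed=0)
        assert res.es > 0.9
        assert res.pvalue < 0.01  # beats every same-sign null draw

    def test_same_seed_reproduces_p(self):
        rng = np.random.default_rng(3)
        metric = np.sort(rng.normal(size=50))[::-1]
        ranked = RankedList([f"g{i}" for i in range(50)], metric)
        members = ["g3", "g7", "g20", "g40"]
        r1 = gsea_permutation_p(ranked, members, n_perm=200, seed=5)
        r2 = gsea_permutation_p(ranked, members, n_perm=200, seed=5)
        assert r1.pvalue == r2.pvalue and r1.nes == r2.nes

    def test_set_as_large_as_universe_rejected(self):
        ranked = RankedList(["a", "b", "c"], np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValidationError):
            gsea_permutation_p(ranked, ["a", "b", "c"], n_perm=100)


class TestOra:
    def test_complete_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        catalog = GeneSetCatalog([GeneSet("S", "", tuple(universe[:5]))])
        result = ora_hypergeometric(universe[:5], catalog, universe)
        assert result.loc["S", "pvalue"] == pytest.approx(1.0 / math.comb(20, 5), rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        catalog = GeneSetCatalog([GeneSet("S", "", tuple(universe[:5]))])
        result = ora_hypergeometric(universe[10:15], catalog, universe)
        assert result.loc["S", "pvalue"] == pytest.approx(1.0)

    def test_matches_pmf_summation_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            N = int(rng.integers(5, 31))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            members = list(rng.choice(universe, size=K, replace=False))
            query = list(rng.choice(universe, size=n, replace=False))
            k = len(set(members) & set(query))
            catalog = GeneSetCatalog([GeneSet("S", "", tuple(members))])
            result = ora_hypergeometric(query, catalog, universe)
            assert result.loc["S", "overlap"] == k
            assert result.loc["S", "pvalue"] == pytest.approx(
                _hypergeom_tail_oracle(N, K, n, k), abs=1e-12
            )

    def test_query_outside_universe_rejected(self):
        catalog = GeneSetCatalog([GeneSet("S", "", ("a",))])
        with pytest.raises(ValidationError):
            ora_hypergeometric({"zz"}, catalog, {"a", "b"})


class TestPathwayCounts:
    def test_counts_significant_sets_only(self):
        import pandas as pd

        catalog = GeneSetCatalog(
            [
                GeneSet("S1", "", ("g1", "g2")),
                GeneSet("S2", "", ("g1",)),
                GeneSet("S3", "", ("g1", "g3")),
            ]
        )
        ora = pd.DataFrame(
            {"padj": [0.01, 0.2, 0.04]}, index=pd.Index(["S1", "S2", "S3"], name="set")
        )
        counts = pathway_membership_counts(["g1", "g2", "g4"], ora, catalog)
        assert counts == {"g1": 2, "g2": 1, "g4": 0}

    def test_planted_key_genes_attain_top_counts(self):
        cohorts, truth = simulate_paired_cohorts(default_config(seed=3))
        catalog = simulate_gene_sets(truth, seed=1)
        universe = set(truth.gene_ids)
        query = truth.shared_de("up")
        ora = ora_hypergeometric(query, catalog, universe)
        counts = pathway_membership_counts(query, ora, catalog)
        up_keys = [k for k in truth.key_genes if truth.module_of[k] == 1]
        threshold = sorted(counts.values(), reverse=True)[len(up_keys) - 1]
        assert all(counts[k] >= threshold for k in up_keys)
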