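import numpy as np
import pytest

from mdconet import (
    ExpressionMatrix,
    adjacency,
    detect_modules,
    kme,
    module_eigengenes,
    pick_soft_power,
    simulate_cohort,
    topological_overlap,
    variance_filter,
)
from mdconet.io import ValidationError
from mdconet.network import ModulePartition, scale_free_fit
from mdconet import default_config

from conftest import single_module_config


def _tom_oracle(a: np.ndarray) -> np.ndarray:
    """O(n^3) direct summation of the topological overlap formula."""
    n = a.shape[0]
    k = a.sum(axis=0)
    tom = np.empty_like(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                tom[i, j] = 1.0
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n))
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def _random_adjacency(rng, n=20):
    raw = rng.uniform(size=(n, n))
    a = (raw + raw.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def _matrix(values, prefix="G"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"S{j}" for j in range(values.shape[1])],
        values,
    )


class TestVarianceFilter:
    def test_keeps_highest_variance_genes(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(4, 40))
        values = base * np.array([1.0, 2.0, 3.0, 4.0])[:, None] ** 0.5
        mat = _matrix(values)
        kept = variance_filter(mat, 0.75)
        assert kept.n_genes == 3
        assert "G0" not in kept.genes

    def test_keep_everything_is_identity(self, toy_matrix):
        kept = variance_filter(toy_matrix, 1.0)
        assert kept.genes == toy_matrix.genes
        assert np.array_equal(kept.values, toy_matrix.values)

    def test_ties_resolved_lexicographically(self):
        values = np.vstack([np.arange(6.0)] * 3)  # identical variances
        mat = ExpressionMatrix(["Gc", "Ga", "Gb"], [f"S{j}" for j in range(6)], values)
        kept = variance_filter(mat, 0.4)  # ceil(0.4*3) = 2 genes
        assert set(kept.genes) == {"Ga", "Gb"}


class TestAdjacency:
    def test_perfectly_correlated_genes(self):
        x = np.arange(10.0)
        mat = _matrix(np.vstack([x, 2 * x + 1]))
        a = adjacency(mat, 6)
        assert a[0, 1] == pytest.approx(1.0)
        assert a[0, 0] == 0.0

    def test_power_shrinks_moderate_correlations(self):
        rng = np.random.default_rng(1)
        mat = _matrix(rng.normal(size=(5, 30)))
        a1 = adjacency(mat, 1)
        a6 = adjacency(mat, 6)
        assert np.allclose(a6, a1**6, atol=1e-12)
        assert 0.5**6 == pytest.approx(0.015625)

    def test_symmetry_and_constant_gene_error(self):
        rng = np.random.default_rng(2)
        mat = _matrix(rng.normal(size=(6, 20)))
        a = adjacency(mat, 4)
        assert np.array_equal(a, a.T)
        bad = _matrix(np.vstack([np.ones(20), rng.normal(size=20)]))
        with pytest.raises(ValidationError, match="G0"):
            adjacency(bad, 2)


class TestTopologicalOverlap:
    def test_zero_adjacency_gives_zero_overlap(self):
        tom = topological_overlap(np.zeros((4, 4)))
        assert np.allclose(tom - np.eye(4), 0.0)

    def test_three_gene_clique(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = topological_overlap(a)
        # (l + a) / (min(k) + 1 - a) = (1 + 1) / (2 + 1 - 1) = 1
        assert np.allclose(tom, 1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = _random_adjacency(rng)
            assert np.allclose(topological_overlap(a), _tom_oracle(a), atol=1e-12)

    def test_asymmetric_input_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValidationError):
            topological_overlap(a)


class TestModuleDetection:
    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        from mdconet import SimulationConfig

        cfg = SimulationConfig(
            n_genes=80,
            module_sizes=[40, 40],
            module_rho=[(0.8, 0.8), (0.8, 0.8)],
            module_factor_shift=[0.0, 0.0],
            samples_per_condition=[(30, 30)],
            seed=4,
        )
        mat, _ = simulate_cohort(cfg, 0)
        tom = topological_overlap(adjacency(mat, 6))
        part = detect_modules(1.0 - tom, mat, min_module_size=10, merge_cut=0.25)
        truth = np.array([cfg.module_of()[g] for g in mat.genes])
        assert part.n_modules == 2
        assert adjusted_rand_score(truth, part.labels) == 1.0

    def test_duplicated_module_merges(self):
        # two "modules" driven by the same factor have eigengene
        # dissimilarity ~0 < 0.25 and must merge into one
        rng = np.random.default_rng(5)
        factor = rng.normal(size=40)
        values = 0.95 * factor + 0.1 * rng.normal(size=(60, 40))
        mat = _matrix(values)
        tom = topological_overlap(adjacency(mat, 6))
        part = detect_modules(1.0 - tom, mat, min_module_size=5, merge_cut=0.25)
        assert part.n_modules == 1

    def test_min_module_size_larger_than_clusters(self, caplog):
        rng = np.random.default_rng(6)
        mat = _matrix(rng.normal(size=(30, 20)))
        tom = topological_overlap(adjacency(mat, 6))
        with caplog.at_level("WARNING"):
            part = detect_modules(1.0 - tom, mat, min_module_size=200, merge_cut=0.25)
        assert part.n_modules == 0
        assert (part.labels == 0).all()


class TestEigengenes:
    def test_rank_one_module(self):
        x = np.arange(12.0)
        mat = _matrix(np.vstack([x, x, x]))
        part = ModulePartition(mat.genes, np.array([1, 1, 1]))
        eig = module_eigengenes(mat, part)
        table = kme(mat, eig)
        assert np.allclose(table["ME1"], 1.0)
        assert eig.variance_explained[1] == pytest.approx(1.0)
        assert np.linalg.norm(eig.eigengene(1)) == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            g, s = int(rng.integers(3, 12)), int(rng.integers(6, 20))
            values = rng.normal(size=(g, s))
            mat = _matrix(values)
            part = ModulePartition(mat.genes, np.ones(g, dtype=int))
            eig = module_eigengenes(mat, part)
            z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1)[:, None]
            # eigenvector of the sample x sample Gram matrix: independent route
            w, v = np.linalg.eigh(z.T @ z)
            leading = v[:, -1]
            cor = abs(np.corrcoef(eig.eigengene(1), leading)[0, 1])
            assert cor > 1 - 1e-10

    def test_sign_orientation_flips_with_members(self):
        rng = np.random.default_rng(8)
        factor = rng.normal(size=30)
        values = 0.9 * factor + 0.2 * rng.normal(size=(5, 30))
        mat = _matrix(values)
        part = ModulePartition(mat.genes, np.ones(5, dtype=int))
        eig_plus = module_eigengenes(mat, part)
        eig_minus = module_eigengenes(_matrix(-values), part)
        assert np.allclose(eig_plus.eigengene(1), -eig_minus.eigengene(1), atol=1e-9)

    def test_variance_explained_equals_mean_squared_kme(self):
        # with per-gene standardization the leading singular share equals
        # the mean squared member kME
        rng = np.random.default_rng(9)
        values = rng.normal(size=(8, 25)) + rng.normal(size=25) * 0.8
        mat = _matrix(values)
        part = ModulePartition(mat.genes, np.ones(8, dtype=int))
        eig = module_eigengenes(mat, part)
        table = kme(mat, eig)
        assert eig.variance_explained[1] == pytest.approx(
            float((table["ME1"] ** 2).mean()), abs=1e-9
        )


class TestKme:
    def test_bounded_and_background_gene_is_no_hub(self):
        cfg = single_module_config(0.81, 0.81, size=30, n_per_condition=20, seed=10,
                                   n_background=5)
        mat, _ = simulate_cohort(cfg, 0)
        part = ModulePartition(
            mat.genes, np.array([1] * 30 + [0] * 5)
        )
        eig = module_eigengenes(mat, part)
        table = kme(mat, eig)
        assert ((table["ME1"] >= -1) & (table["ME1"] <= 1)).all()
        background = table.iloc[30:]["ME1"].abs()
        assert (background < 0.85).all()
        members = table.iloc[:30]["ME1"]
        assert members.mean() > 0.8


class TestSoftPower:
    def test_single_candidate_is_returned(self):
        rng = np.random.default_rng(11)
        mat = _matrix(rng.normal(size=(60, 20)))
        assert pick_soft_power(mat, candidate_powers=[7]) == 7

    def test_deterministic(self):
        mat, _ = simulate_cohort(default_config(seed=5), 0)
        filtered = variance_filter(mat, 0.75)
        assert pick_soft_power(filtered) == pick_soft_power(filtered)

    def test_planted_structure_reaches_scale_free_target(self):
        mat, _ = simulate_cohort(default_config(seed=0), 0)
        filtered = variance_filter(mat, 0.75)
        power = pick_soft_power(filtered)
        k = adjacency(filtered, power).sum(axis=0)
        assert scale_free_fit(k) >= 0.8
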