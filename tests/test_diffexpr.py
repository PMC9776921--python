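import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from mdconet import (
    ExpressionMatrix,
    SampleLabels,
    bh_adjust,
    common_pattern_genes,
    select_top_k,
    significant_genes,
    simulate_paired_cohorts,
    two_group_test,
)
from mdconet.io import ValidationError
from mdconet.simulate import DEGene, SimulationConfig


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force step-up rule: adj_(i) = min over j >= i of p_(j) * m / j."""
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank_pos - 1, m)]
        adjusted[idx] = min(1.0, min(tail))
    return adjusted


def _two_group_matrix(xa: np.ndarray, xb: np.ndarray):
    values = np.hstack([xa, xb])
    samples = [f"A{i}" for i in range(xa.shape[1])] + [f"B{i}" for i in range(xb.shape[1])]
    mat = ExpressionMatrix([f"G{i}" for i in range(values.shape[0])], samples, values)
    labels = SampleLabels(
        {s: ("A" if s.startswith("A") else "B") for s in samples}
    )
    return mat, labels


class TestWelch:
    def test_identical_groups_give_null_result(self):
        x = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 9.0]])
        mat, labels = _two_group_matrix(x, x)  # group B duplicates group A
        de = two_group_test(mat, labels)
        assert np.allclose(de["log2fc"], 0.0)
        assert np.allclose(de["pvalue"], 1.0)

    def test_constant_equal_gene_degenerates_to_p_one(self):
        xa = np.vstack([np.full(4, 5.0), np.arange(4.0)])
        xb = np.vstack([np.full(4, 5.0), np.arange(4.0) + 1])
        mat, labels = _two_group_matrix(xa, xb)
        de = two_group_test(mat, labels)
        assert de.loc["G0", "log2fc"] == 0.0
        assert de.loc["G0", "stat"] == 0.0
        assert de.loc["G0", "pvalue"] == 1.0

    def test_large_effect_is_detected(self):
        rng = np.random.default_rng(0)
        xa = np.vstack([rng.normal(0.0, 1.0, size=50), rng.normal(size=50)])
        xb = np.vstack([rng.normal(3.0, 1.0, size=50), rng.normal(size=50)])
        mat, labels = _two_group_matrix(xa, xb)
        de = two_group_test(mat, labels)
        assert de.loc["G0", "pvalue"] < 1e-10
        assert de.loc["G0", "log2fc"] == pytest.approx(3.0, abs=0.5)

    def test_label_swap_negates_log2fc_and_keeps_p(self):
        rng = np.random.default_rng(1)
        xa = rng.normal(size=(20, 10))
        xb = rng.normal(size=(20, 12)) + 0.5
        mat, labels = _two_group_matrix(xa, xb)
        swapped = SampleLabels(
            {s: ("B" if c == "A" else "A") for s, c in labels.mapping.items()}
        )
        de = two_group_test(mat, labels)
        de_sw = two_group_test(mat, swapped)
        assert np.allclose(de["log2fc"].values, -de_sw["log2fc"].values)
        assert np.allclose(de["pvalue"].values, de_sw["pvalue"].values)

    def test_null_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(3)
        xa = rng.normal(size=(2000, 15))
        xb = rng.normal(size=(2000, 15))
        mat, labels = _two_group_matrix(xa, xb)
        de = two_group_test(mat, labels)
        frac = float((de["pvalue"] < 0.05).mean())
        assert 0.035 <= frac <= 0.065


class TestBenjaminiHochberg:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValidationError):
            bh_adjust([-0.1])

    def test_matches_brute_force_oracle_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.array_equal(bh_adjust(p), _bh_oracle(p))

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.uniform(size=200)
            expected = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=500)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1.0).all()


class TestTopKSelection:
    @staticmethod
    def _de_frame(rows):
        import pandas as pd

        frame = pd.DataFrame(
            rows, columns=["gene", "log2fc", "stat", "pvalue", "padj"]
        ).set_index("gene")
        return frame

    def test_short_pool_returns_everything_in_order(self):
        de = self._de_frame(
            [(f"G{i}", 1.0 + i, 5.0, 0.0001 * (i + 1), 0.001 * (i + 1)) for i in range(10)]
        )
        out = select_top_k(de, 500, "up")
        assert out == [f"G{i}" for i in range(10)]

    def test_tie_broken_by_absolute_fold_change(self):
        de = self._de_frame(
            [("Gsmall", 1.0, 3.0, 0.01, 0.02), ("Gbig", 2.0, 3.0, 0.01, 0.02)]
        )
        assert select_top_k(de, 2, "up") == ["Gbig", "Gsmall"]

    def test_no_significant_gene_returns_empty_with_warning(self, caplog):
        de = self._de_frame([("G1", 2.0, 1.0, 0.5, 0.6), ("G2", 1.0, 1.0, 0.4, 0.6)])
        with caplog.at_level("WARNING"):
            assert select_top_k(de, 10, "up") == []
        assert any("up-regulated" in r.message for r in caplog.records)

    def test_direction_and_alpha_gate(self):
        de = self._de_frame(
            [("Gup", 2.0, 5.0, 0.001, 0.01), ("Gdown", -2.0, -5.0, 0.001, 0.01)]
        )
        assert select_top_k(de, 5, "up") == ["Gup"]
        assert select_top_k(de, 5, "down") == ["Gdown"]

    def test_fold_change_filter_on_deg_definition(self):
        de = self._de_frame(
            [("Gbig", 1.5, 5.0, 1e-4, 1e-3), ("Gsmall", 0.5, 5.0, 1e-4, 1e-3)]
        )
        kept = significant_genes(de, alpha=0.05, fc_threshold=2.0)
        assert list(kept.index) == ["Gbig"]  # |log2fc| > 1 required


class TestCommonPattern:
    def test_intersection(self):
        lists = common_pattern_genes(
            (["G1", "G2", "G3"], ["D1"]), (["G2", "G3", "G4"], ["D2"])
        )
        assert lists.common_up == {"G2", "G3"}
        assert lists.common_down == set()

    def test_disjoint_lists_warn(self, caplog):
        with caplog.at_level("WARNING"):
            lists = common_pattern_genes((["G1"], ["G2"]), (["G3"], ["G4"]))
        assert lists.common_up == set() and lists.common_down == set()
        assert any("empty" in r.message for r in caplog.records)

    def test_planted_shared_de_genes_are_recovered(self):
        # strong shared shifts on background genes, no modules: the
        # cross-cohort intersection must contain every planted gene
        genes_up = [f"G{i:04d}" for i in range(50)]
        genes_down = [f"G{i:04d}" for i in range(50, 100)]
        cfg = SimulationConfig(
            n_genes=500,
            module_sizes=[],
            module_rho=[],
            module_factor_shift=[],
            samples_per_condition=[(30, 30), (25, 25)],
            de_genes=tuple(
                [DEGene(g, +2.0) for g in genes_up]
                + [DEGene(g, -2.0) for g in genes_down]
            ),
            seed=11,
        )
        cohorts, truth = simulate_paired_cohorts(cfg)
        tops = []
        for mat, lab in cohorts:
            de = two_group_test(mat, lab)
            tops.append(
                (select_top_k(de, 500, "up"), select_top_k(de, 500, "down"))
            )
        common = common_pattern_genes(tops[0], tops[1], k=500)
        assert common.common_up >= set(genes_up)
        assert common.common_down >= set(genes_down)
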