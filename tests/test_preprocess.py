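"""QC filtering, normalization, cell-cycle scoring, regression, HVG selection."""

import numpy as np
import pytest

from serocell.core import AllFilteredError, CountMatrix, GeneSet, SerocellError
from serocell.preprocess import (
    NormalizedMatrix,
    cell_cycle_score,
    filter_matrix,
    log_normalize,
    regress_covariates,
    scale_and_clip,
    select_variable_genes,
)


def random_counts(seed, n_genes=300, n_cells=300, density=0.2, high=6):
    rng = np.random.default_rng(seed)
    mat = rng.integers(1, high, size=(n_genes, n_cells)) * (
        rng.random((n_genes, n_cells)) < density
    )
    return CountMatrix(
        [f"g{i}" for i in range(n_genes)], [f"c{j}" for j in range(n_cells)], mat
    )


class TestFilter:
    def test_gene_detected_in_too_few_cells_removed(self):
        mat = np.zeros((5, 5), dtype=int)
        mat[0, :2] = 1  # gene A: 2 cells < min_cells=3
        mat[1:, :] = 1
        cm = CountMatrix([f"g{i}" for i in range(5)], [f"c{j}" for j in range(5)], mat)
        out, report = filter_matrix(cm, min_cells=3, min_genes=1)
        assert "g0" not in out.genes and report["genes_removed"] == 1

    def test_cell_boundary_at_min_genes(self):
        n = 250
        mat = np.ones((n, 3), dtype=int)
        mat[199:, 1] = 0  # cell 2 detects exactly 199 genes
        mat[200:, 2] = 0  # cell 3 detects exactly 200
        cm = CountMatrix([f"g{i}" for i in range(n)], ["a", "b", "c"], mat)
        out, _ = filter_matrix(cm, min_cells=1, min_genes=200)
        assert out.barcodes == ["a", "c"]

    def test_matches_brute_force_two_pass_recount(self):
        cm = random_counts(0)
        out, _ = filter_matrix(cm, min_cells=3, min_genes=50)
        dense = cm.counts.toarray()
        gene_keep = (dense > 0).sum(axis=1) >= 3
        cell_keep = (dense[gene_keep] > 0).sum(axis=0) >= 50
        assert out.genes == [g for g, k in zip(cm.genes, gene_keep) if k]
        assert out.barcodes == [b for b, k in zip(cm.barcodes, cell_keep) if k]

    def test_idempotent(self):
        cm = random_counts(1)
        once, _ = filter_matrix(cm, min_cells=3, min_genes=50)
        twice, report = filter_matrix(once, min_cells=3, min_genes=50)
        assert report["genes_removed"] == 0 and report["cells_removed"] == 0
        assert (once.counts != twice.counts).nnz == 0

    def test_all_filtered_raises(self):
        cm = CountMatrix(["g0"], ["c0", "c1"], np.array([[1, 0]]))
        with pytest.raises(AllFilteredError):
            filter_matrix(cm, min_cells=5, min_genes=1)


class TestLogNormalize:
    def test_closed_form_value(self):
        mat = np.array([[100], [9900]])
        cm = CountMatrix(["a", "b"], ["c"], mat)
        norm = log_normalize(cm, scale_factor=10_000)
        assert norm.values[0, 0] == pytest.approx(np.log(101), abs=1e-12)

    def test_zero_count_stays_zero_and_monotone_within_cell(self):
        cm = random_counts(2)
        norm = log_normalize(cm)
        dense = cm.counts.toarray()
        assert np.all(norm.values[dense == 0] == 0)
        col = 0
        order = np.argsort(dense[:, col], kind="stable")
        assert np.all(np.diff(norm.values[order, col]) >= 0)

    def test_depth_invariance_doubling_a_cell(self):
        mat = np.array([[3, 6], [7, 14]])
        cm = CountMatrix(["a", "b"], ["c1", "c2"], mat)
        norm = log_normalize(cm)
        assert np.allclose(norm.values[:, 0], norm.values[:, 1])


class TestCellCycle:
    def test_zero_expression_set_scores_nonpositive(self):
        rng = np.random.default_rng(0)
        values = rng.random((100, 40))
        values[:5] = 0.0
        norm = NormalizedMatrix(
            [f"g{i}" for i in range(100)], [f"c{j}" for j in range(40)], values
        )
        s = GeneSet("S", ["g0", "g1", "g2"])
        g2m = GeneSet("G2M", ["g3", "g4"])
        scores = cell_cycle_score(norm, s, g2m, seed=0)
        assert np.all(scores.s_score <= 0) and np.all(scores.g2m_score <= 0)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(1)
        values = rng.random((60, 30))
        genes = [f"g{i}" for i in range(60)]
        norm = NormalizedMatrix(genes, [f"c{j}" for j in range(30)], values)
        perm = rng.permutation(60)
        norm_p = NormalizedMatrix(
            [genes[i] for i in perm], list(norm.barcodes), values[perm]
        )
        s, g2m = GeneSet("S", ["g5", "g6"]), GeneSet("G2M", ["g7", "g8"])
        a = cell_cycle_score(norm, s, g2m, seed=0)
        b = cell_cycle_score(norm_p, s, g2m, seed=0)
        assert np.allclose(a.s_score, b.s_score)
        assert np.allclose(a.g2m_score, b.g2m_score)

    def test_elevated_set_cells_score_higher(self):
        rng = np.random.default_rng(2)
        values = rng.random((200, 80))
        values[:10, :40] += 1.0  # first 40 cells cycling
        norm = NormalizedMatrix(
            [f"g{i}" for i in range(200)], [f"c{j}" for j in range(80)], values
        )
        s = GeneSet("S", [f"g{i}" for i in range(10)])
        g2m = GeneSet("G2M", [f"g{i}" for i in range(10, 20)])
        scores = cell_cycle_score(norm, s, g2m, seed=0)
        assert scores.s_score[:40].mean() > scores.s_score[40:].mean()

    def test_disjoint_set_raises(self):
        norm = NormalizedMatrix(["g0"], ["c0"], np.zeros((1, 1)))
        with pytest.raises(SerocellError):
            cell_cycle_score(norm, GeneSet("S", ["nope"]), GeneSet("G2M", ["g0"]))


class TestRegression:
    def _norm(self, seed, n_genes=50, n_cells=200):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(n_genes, n_cells))
        return (
            NormalizedMatrix(
                [f"g{i}" for i in range(n_genes)],
                [f"c{j}" for j in range(n_cells)],
                values,
            ),
            rng,
        )

    def test_exact_linear_dependence_gives_zero_residuals(self):
        rng = np.random.default_rng(3)
        totals = rng.integers(500, 5000, size=100)
        values = np.outer(np.ones(5), 2.0 * np.log10(totals) + 1.0)
        norm = NormalizedMatrix(
            [f"g{i}" for i in range(5)], [f"c{j}" for j in range(100)], values
        )
        out = regress_covariates(norm, totals, rng.normal(size=100), rng.normal(size=100))
        assert np.max(np.abs(out.values)) < 1e-8

    def test_residuals_orthogonal_to_design_and_zero_mean(self):
        norm, rng = self._norm(4)
        totals = rng.integers(500, 5000, size=200)
        s, g2m = rng.normal(size=200), rng.normal(size=200)
        out = regress_covariates(norm, totals, s, g2m)
        design = np.column_stack([np.ones(200), np.log10(totals), s, g2m])
        dots = out.values @ design
        assert np.max(np.abs(dots)) < 1e-6
        assert np.max(np.abs(out.values.mean(axis=1))) < 1e-8

    def test_constant_covariate_dropped_with_warning(self, caplog):
        norm, rng = self._norm(5)
        totals = rng.integers(500, 5000, size=200)
        with caplog.at_level("WARNING"):
            out = regress_covariates(norm, totals, np.zeros(200), rng.normal(size=200))
        assert "constant" in caplog.text
        assert out.provenance["regressed"] == ["log10_total_umis", "g2m_score"]


class TestVariableGenes:
    def test_bimodal_gene_selected(self):
        rng = np.random.default_rng(6)
        found = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            values = np.log1p(rng.poisson(2.0, size=(100, 200))).astype(float)
            bimodal = np.r_[rng.poisson(0.2, 100), rng.poisson(8.0, 100)]
            values[0] = np.log1p(bimodal)
            norm = NormalizedMatrix(
                [f"g{i}" for i in range(100)], [f"c{j}" for j in range(200)], values
            )
            if "g0" in select_variable_genes(norm, n_bins=10):
                found += 1
        assert found >= 19

    def test_too_few_genes_raises(self):
        norm = NormalizedMatrix(
            [f"g{i}" for i in range(5)], ["c0", "c1"], np.random.default_rng(0).random((5, 2))
        )
        with pytest.raises(SerocellError):
            select_variable_genes(norm, n_bins=20)

    def test_constant_matrix_returns_empty_with_warning(self, caplog):
        norm = NormalizedMatrix(
            [f"g{i}" for i in range(30)], [f"c{j}" for j in range(10)], np.ones((30, 10))
        )
        with caplog.at_level("WARNING"):
            assert select_variable_genes(norm, n_bins=5) == []
        assert "constant" in caplog.text

    def test_null_selection_rate_near_gaussian_tail(self):
        """On i.i.d. genes the selected fraction tracks P(Z >= 1) ~ 0.16."""
        fracs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            values = np.log1p(rng.poisson(1.5, size=(1000, 150))).astype(float)
            norm = NormalizedMatrix(
                [f"g{i}" for i in range(1000)], [f"c{j}" for j in range(150)], values
            )
            fracs.append(len(select_variable_genes(norm)) / 1000)
        assert 0.08 <= np.mean(fracs) <= 0.25


def test_scale_and_clip_bounds_and_standardizes():
    rng = np.random.default_rng(7)
    values = rng.normal(3.0, 2.0, size=(40, 500))
    values[0, 0] = 1e4
    norm = NormalizedMatrix(
        [f"g{i}" for i in range(40)], [f"c{j}" for j in range(500)], values
    )
    out = scale_and_clip(norm, clip=10.0)
    assert np.max(np.abs(out.values)) <= 10.0
    assert abs(out.values[5].mean()) < 1e-9
    assert out.values[5].std() == pytest.approx(1.0, abs=1e-9)
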