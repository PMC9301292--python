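"""QC filtering and Wilcoxon differential expression."""

import numpy as np
import pytest
from scipy import stats

from herbnet.deg import (
    EmptyMatrixError,
    LabeledExpressionMatrix,
    lognormalize,
    qc_filter,
    wilcoxon_deg,
)
from herbnet.simulate import SimulationConfig, gen_sc_counts

from oracles import exact_wilcoxon_p


def small_matrix(counts, groups=None):
    counts = np.asarray(counts, dtype=float)
    n_cells, n_genes = counts.shape
    if groups is None:
        groups = ["disease"] * (n_cells // 2) + ["control"] * (n_cells - n_cells // 2)
    return LabeledExpressionMatrix(
        counts=counts,
        gene_names=np.array([f"G{i}" for i in range(n_genes)], dtype=object),
        cell_group=np.array(groups, dtype=object),
        cell_lineage=np.array(["L"] * n_cells, dtype=object),
        mito_flag=np.zeros(n_genes, dtype=bool),
    )


class TestQcFilter:
    def test_gene_detected_in_nine_cells_removed_ten_kept(self):
        counts = np.zeros((30, 2))
        counts[:9, 0] = 1   # below the 10-cell floor
        counts[:10, 1] = 1  # at the floor
        counts[:, 1] += 0   # keep cells alive through gene 1
        mat = small_matrix(counts)
        out = qc_filter(mat, min_genes=1)
        assert list(out.gene_names) == ["G1"]

    def test_cell_thresholds(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(40, 300))
        mito = np.zeros(300, dtype=bool)
        mito[:5] = True
        counts[0] = 0
        counts[0, :199] = 1          # 199 detected genes: removed
        counts[1] = 0
        counts[1, :200] = 1          # exactly 200 detected, 0% mito: kept
        counts[2, mito] = 10_000     # mito-dominated: removed
        mat = LabeledExpressionMatrix(
            counts=counts,
            gene_names=np.array([f"G{i}" for i in range(300)], dtype=object),
            cell_group=np.array(["disease", "control"] * 20, dtype=object),
            cell_lineage=np.array(["L"] * 40, dtype=object),
            mito_flag=mito,
        )
        out = qc_filter(mat)
        # all genes survive (poisson mean 3 over 40 cells), so detected
        # counts are comparable before/after
        kept = set(range(40)) - {0, 2}
        assert out.n_cells == len(kept)

    def test_matches_independent_threshold_check(self, rng):
        counts = rng.negative_binomial(2, 0.4, size=(500, 300)).astype(float)
        zero_rows = rng.choice(500, size=20, replace=False)
        counts[zero_rows] = 0
        counts[zero_rows, :50] = 1
        mito = np.zeros(300, dtype=bool)
        mito[rng.choice(300, 10, replace=False)] = True
        mat = LabeledExpressionMatrix(
            counts=counts,
            gene_names=np.array([f"G{i}" for i in range(300)], dtype=object),
            cell_group=np.array(["disease", "control"] * 250, dtype=object),
            cell_lineage=np.array(["L"] * 500, dtype=object),
            mito_flag=mito,
        )
        out = qc_filter(mat, min_cells=10, min_genes=150, max_mito_frac=0.3)
        gene_keep = (counts > 0).sum(axis=0) >= 10
        sub = counts[:, gene_keep]
        cell_keep = []
        for i in range(500):
            det = (sub[i] > 0).sum()
            tot = sub[i].sum()
            mfrac = sub[i, mito[gene_keep]].sum() / tot if tot else 1.0
            cell_keep.append(det >= 150 and mfrac < 0.3)
        assert out.n_genes == gene_keep.sum()
        assert out.n_cells == sum(cell_keep)

    def test_empty_result_raises(self):
        mat = small_matrix(np.ones((4, 3)))
        with pytest.raises(EmptyMatrixError):
            qc_filter(mat)  # genes in only 4 cells


class TestWilcoxonDeg:
    def test_identical_gene_is_filtered(self):
        counts = np.ones((10, 1)) * 4
        res = wilcoxon_deg(small_matrix(counts))
        assert res == []

    def test_p_matches_exact_enumeration_eight_vs_eight(self, rng):
        counts = rng.poisson(5.0, size=(16, 2)).astype(float) + 1
        counts[:8, 0] += rng.integers(0, 4, size=8)
        mat = small_matrix(counts)
        res = [r for r in wilcoxon_deg(mat, min_pct=0.0, min_abs_logfc=0.0)
               if r.gene == "G0"]
        assert len(res) == 1
        norm = lognormalize(counts)
        exact = exact_wilcoxon_p(norm[:8, 0], norm[8:, 0])
        assert res[0].p_value == pytest.approx(exact, abs=0.02)

    def test_label_swap_negates_logfc_and_keeps_p(self, rng):
        counts = rng.poisson(4.0, size=(30, 20)).astype(float)
        counts[:15, :5] *= 4
        mat = small_matrix(counts)
        swapped = small_matrix(counts, groups=["control"] * 15 + ["disease"] * 15)
        res_a = {r.gene: r for r in wilcoxon_deg(mat, min_pct=0, min_abs_logfc=0)}
        res_b = {r.gene: r for r in wilcoxon_deg(swapped, min_pct=0, min_abs_logfc=0)}
        assert set(res_a) == set(res_b)
        for g in res_a:
            assert res_a[g].log_fc == pytest.approx(-res_b[g].log_fc, abs=1e-12)
            assert res_a[g].p_value == pytest.approx(res_b[g].p_value, rel=1e-9)
            assert {res_a[g].direction, res_b[g].direction} == {"up", "down"} or \
                res_a[g].log_fc == 0

    def test_p_invariant_under_monotone_transform(self, rng):
        """The rank-sum p ignores any strictly monotone rescaling."""
        counts = rng.poisson(6.0, size=(20, 5)).astype(float)
        mat = small_matrix(counts)
        base = {r.gene: r.p_value
                for r in wilcoxon_deg(mat, min_pct=0, min_abs_logfc=0)}
        norm = lognormalize(counts)
        for j in range(5):
            x, y = norm[:10, j], norm[10:, j]
            fx, fy = np.exp(3 * x) + 1, np.exp(3 * y) + 1
            p = stats.mannwhitneyu(fx, fy, alternative="two-sided",
                                   method="asymptotic").pvalue
            if f"G{j}" in base:
                assert base[f"G{j}"] == pytest.approx(p, rel=1e-9)

    def test_missing_group_raises(self):
        counts = np.ones((6, 2))
        mat = small_matrix(counts, groups=["disease"] * 6)
        with pytest.raises(ValueError):
            wilcoxon_deg(mat)

    def test_planted_de_recovery(self):
        matrix, truth = gen_sc_counts(SimulationConfig(seed=11))
        matrix = qc_filter(matrix)
        hits = {r.gene for r in wilcoxon_deg(matrix)}
        planted = set(truth.loc[truth.is_de, "gene"])
        assert len(hits & planted) >= 45
        assert len(hits - planted) <= 5

    def test_per_lineage_union_contains_strong_genes(self, rng):
        counts = rng.poisson(4.0, size=(40, 10)).astype(float)
        counts[:20, 0] *= 8
        mat = LabeledExpressionMatrix(
            counts=counts,
            gene_names=np.array([f"G{i}" for i in range(10)], dtype=object),
            cell_group=np.array(["disease"] * 20 + ["control"] * 20, dtype=object),
            cell_lineage=np.array((["A"] * 10 + ["B"] * 10) * 2, dtype=object),
            mito_flag=np.zeros(10, dtype=bool),
        )
        pooled = {r.gene for r in wilcoxon_deg(mat)}
        unioned = {r.gene for r in wilcoxon_deg(mat, per_lineage=True)}
        assert "G0" in pooled and "G0" in unioned
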