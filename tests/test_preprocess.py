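"""Filtering and differential-expression behavior."""

import numpy as np
import pandas as pd
import pytest

import swimnet as sw
from swimnet.preprocess import NoGenesError, gene_iqr

from conftest import make_matrix


class TestFilterLowExpression:
    def test_all_zero_gene_removed(self):
        values = np.vstack([np.zeros(6), np.arange(6) + 1.0, 2.0 * np.arange(6) + 1.0])
        mat = make_matrix(values, ["z", "a", "b"], 3, 3)
        out = sw.filter_low_expression(mat, max_zero_samples=5, iqr_percentile=0)
        assert out.gene_ids == ["a", "b"]

    def test_constant_gene_removed_by_iqr(self):
        values = np.vstack([np.full(6, 7.0), np.arange(6), np.arange(6) * 2, np.arange(6) * 3])
        mat = make_matrix(values, ["const", "a", "b", "c"], 3, 3)
        out = sw.filter_low_expression(mat, max_zero_samples=6, iqr_percentile=25)
        assert "const" not in out.gene_ids

    def test_iqr_percentile_against_sort_oracle(self):
        # four genes with IQRs 0, 1, 2, 3; the 50th percentile of the IQRs
        # is 1.5, so exactly the two most variable genes survive
        # evenly spaced rows: IQR of c * arange(8) is 3.5 c
        rows = [np.full(8, 5.0)] + [5 + (s / 3.5) * np.arange(8) for s in (1.0, 2.0, 3.0)]
        mat = make_matrix(np.vstack(rows), ["g0", "g1", "g2", "g3"], 4, 4)
        iqrs = gene_iqr(mat.values)
        assert list(iqrs.round(6)) == [0.0, 1.0, 2.0, 3.0]
        # independent oracle: sort the IQRs and interpolate the median
        srt = np.sort(iqrs.to_numpy())
        oracle_cut = srt[1] + 0.5 * (srt[2] - srt[1])
        out = sw.filter_low_expression(mat, max_zero_samples=8, iqr_percentile=50)
        assert out.gene_ids == [g for g in mat.gene_ids if iqrs[g] >= oracle_cut] == ["g2", "g3"]

    def test_zero_filter_idempotent(self, small_matrix):
        # the percentile stage is relative and tightens on re-application,
        # so idempotence holds for the absolute (zero-count) stage
        once = sw.filter_low_expression(small_matrix, 2, 0)
        twice = sw.filter_low_expression(once, 2, 0)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_empty_result_raises(self, small_matrix):
        zeros = make_matrix(np.zeros((2, 6)), ["a", "b"], 3, 3)
        with pytest.raises(NoGenesError, match="no genes survive"):
            sw.filter_low_expression(zeros, 0, 0)

    def test_negative_threshold_rejected(self, small_matrix):
        with pytest.raises(ValueError):
            sw.filter_low_expression(small_matrix, -1, 10)
        with pytest.raises(ValueError):
            sw.filter_low_expression(small_matrix, 0, -5)


class TestLogFoldChange:
    def test_identical_means_give_zero(self):
        mat = make_matrix(np.tile([1.0, 2.0], (1, 4)), ["g"], 4, 4)
        assert sw.log_fold_change(mat, "g") == pytest.approx(0.0)

    def test_linear_ratio(self):
        mat = make_matrix([[8, 8, 8, 2, 2, 2]], ["g"], 3, 3, scale="linear")
        assert sw.log_fold_change(mat, "g") == pytest.approx(2.0)

    def test_log_scale_difference(self):
        mat = make_matrix([[5.5, 5.5, 5.5, 4.0, 4.0, 4.0]], ["g"], 3, 3, scale="log2")
        assert sw.log_fold_change(mat, "g") == pytest.approx(1.5)

    def test_zero_mean_b_on_linear_scale_raises(self):
        mat = make_matrix([[1, 1, 1, 0, 0, 0]], ["g"], 3, 3, scale="linear")
        with pytest.raises(ValueError, match="condition B"):
            sw.log_fold_change(mat, "g")

    def test_missing_gene_raises_keyerror(self, small_matrix):
        with pytest.raises(KeyError):
            sw.log_fold_change(small_matrix, "nope")


class TestDifferentialExpression:
    def test_planted_signal_recovered(self):
        rng = np.random.default_rng(7)
        values = rng.normal(0, 1, size=(500, 20))
        planted = [f"g{i:03d}" for i in range(50)]
        values[:50, :10] += 3.0  # |log_fc| = 3 on log scale
        mat = make_matrix(values, [f"g{i:03d}" for i in range(500)], 10, 10)
        table = sw.differential_expression(mat, fc_threshold=1.5, fdr_threshold=0.05)
        hits = set(table["gene_id"])
        assert set(planted) <= hits
        # false positives bounded by the BH-controlled expectation
        assert len(hits - set(planted)) <= 0.05 * len(table) + 3

    def test_constant_gene_excluded(self):
        values = np.vstack([np.full(8, 3.0), np.r_[np.full(4, 9.0), np.full(4, 1.0)]])
        table = sw.differential_expression(make_matrix(values, ["flat", "de"], 4, 4), 1.0, 0.05)
        assert list(table["gene_id"]) == ["de"]
        assert table.iloc[0]["direction"] == "up"

    def test_infinite_fc_threshold_empties_table(self, small_matrix):
        table = sw.differential_expression(small_matrix, np.inf, 0.05)
        assert table.empty

    def test_invariant_to_sample_and_gene_order(self, small_matrix):
        base = sw.differential_expression(small_matrix, 0.5, 0.2)
        rng = np.random.default_rng(0)
        cols = list(small_matrix.values.columns)
        rows = list(small_matrix.values.index)
        rng.shuffle(cols)
        rng.shuffle(rows)
        shuffled = sw.ExpressionMatrix(
            values=small_matrix.values.loc[rows, cols],
            condition=small_matrix.condition[cols],
            scale=small_matrix.scale,
        )
        pd.testing.assert_frame_equal(base, sw.differential_expression(shuffled, 0.5, 0.2))

    def test_degenerate_zero_variance_p_values(self):
        values = np.vstack(
            [
                np.r_[np.full(4, 2.0), np.full(4, 2.0)],  # equal constants -> p 1
                np.r_[np.full(4, 5.0), np.full(4, 1.0)],  # distinct constants -> p 0
            ]
        )
        mat = make_matrix(values, ["same", "diff"], 4, 4)
        table = sw.differential_expression(mat, 0.0, 1.01)
        by_gene = table.set_index("gene_id")
        assert by_gene.loc["same", "p_value"] == 1.0
        assert by_gene.loc["diff", "p_value"] == 0.0


def test_bh_adjustment_monotone_in_sorted_p():
    """BH-adjusted values never decrease along the sorted raw p-values."""
    rng = np.random.default_rng(3)
    values = rng.normal(0, 1, size=(80, 12))
    values[:10, :6] += 2.0
    mat = make_matrix(values, [f"g{i}" for i in range(80)], 6, 6)
    table = sw.differential_expression(mat, 0.0, 1.01)
    ordered = table.sort_values("p_value")
    assert np.all(np.diff(ordered["fdr"].to_numpy()) >= -1e-12)
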