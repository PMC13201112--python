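"""Reference centering, genomic smoothing, median filtering, CNV scoring."""

import numpy as np
import pandas as pd
import pytest

from markermeta import (
    GenePosition,
    ValidationError,
    cnv_pipeline,
    gen_single_cell,
    genomic_smooth,
    median_filter_trace,
    reference_center,
    score_cnv,
)


def frame(values, genes=None, cells=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cells)


def linear_positions(genes, chrom="chr1"):
    return [GenePosition(chrom=chrom, start=i * 100, gene=g)
            for i, g in enumerate(genes)]


class TestReferenceCenter:
    def test_reference_profile_maps_to_zero(self):
        rng = np.random.default_rng(0)
        expr = frame(rng.normal(2, 1, (10, 6)))
        centered = reference_center(expr, ["c0", "c1", "c2"])
        np.testing.assert_allclose(
            centered[["c0", "c1", "c2"]].mean(axis=1), 0.0, atol=1e-12)

    def test_shift_in_query_cell_survives(self):
        expr = frame(np.zeros((3, 4)))
        expr.loc["g1", "c3"] = 1.0
        centered = reference_center(expr, ["c0", "c1", "c2"])
        assert centered.loc["g1", "c3"] == pytest.approx(1.0)

    def test_empty_or_unknown_reference_rejected(self):
        expr = frame(np.zeros((2, 2)))
        with pytest.raises(ValidationError):
            reference_center(expr, [])
        with pytest.raises(ValidationError):
            reference_center(expr, ["nope"])


class TestGenomicSmooth:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(1)
        expr = frame(rng.normal(size=(8, 3)))
        pos = linear_positions(expr.index)
        smoothed, _ = genomic_smooth(expr, pos, window=1)
        pd.testing.assert_frame_equal(smoothed, expr)

    def test_constant_signal_unchanged(self):
        expr = frame(np.full((9, 2), 3.5))
        smoothed, _ = genomic_smooth(expr, linear_positions(expr.index), window=5)
        np.testing.assert_allclose(smoothed.to_numpy(), 3.5)

    def test_step_signal_boundary_values(self):
        expr = frame(np.array([[0, 0, 0, 1, 1, 1]], dtype=float).T)
        smoothed, _ = genomic_smooth(expr, linear_positions(expr.index), window=3)
        np.testing.assert_allclose(
            smoothed.to_numpy().ravel(), [0, 0, 1 / 3, 2 / 3, 1, 1])

    def test_no_bleed_across_chromosomes(self):
        genes = [f"g{i}" for i in range(6)]
        pos = (linear_positions(genes[:3], "chr1")
               + [GenePosition("chr2", i * 100, g) for i, g in enumerate(genes[3:])])
        expr = frame(np.array([[0, 0, 0, 5, 5, 5]], dtype=float).T, genes=genes)
        smoothed, _ = genomic_smooth(expr, pos, window=3)
        np.testing.assert_allclose(smoothed.to_numpy().ravel(), [0, 0, 0, 5, 5, 5])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 25))
            window = int(rng.choice([1, 3, 5, 7]))
            values = rng.normal(size=(n, 2))
            expr = frame(values)
            smoothed, _ = genomic_smooth(expr, linear_positions(expr.index), window)
            half = window // 2
            expected = np.array([
                values[max(0, i - half):i + half + 1].mean(axis=0)
                for i in range(n)
            ])
            np.testing.assert_allclose(smoothed.to_numpy(), expected, atol=1e-12)

    def test_even_window_rejected(self):
        expr = frame(np.zeros((4, 1)))
        with pytest.raises(ValidationError):
            genomic_smooth(expr, linear_positions(expr.index), window=2)

    def test_missing_position_rejected(self):
        expr = frame(np.zeros((3, 1)))
        with pytest.raises(ValidationError):
            genomic_smooth(expr, linear_positions(expr.index[:2]), window=1)


class TestMedianFilter:
    def test_width_one_is_identity(self):
        v = np.array([3.0, 1.0, 4.0])
        np.testing.assert_array_equal(median_filter_trace(v, 1), v)

    def test_spike_removed(self):
        v = np.zeros(9)
        v[4] = 10.0
        np.testing.assert_allclose(median_filter_trace(v, 3), 0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            width = int(rng.choice([1, 3, 5, 7]))
            v = rng.normal(size=n)
            got = median_filter_trace(v, width)
            half = width // 2
            expected = np.array([
                np.median(v[max(0, i - half):i + half + 1]) for i in range(n)
            ])
            np.testing.assert_allclose(got, expected)

    def test_even_width_rejected(self):
        with pytest.raises(ValidationError):
            median_filter_trace(np.zeros(5), 4)


class TestScoreCNV:
    def test_reference_cells_score_near_zero(self):
        rng = np.random.default_rng(0)
        n_genes, n_ref = 400, 100
        smoothed = frame(rng.normal(size=(n_genes, n_ref)),
                         cells=[f"r{i}" for i in range(n_ref)])
        result = score_cnv(smoothed, list(smoothed.columns), k_outer=4)
        # ~5% of gene/cell pairs beyond |z| = 2 by chance
        frac_nonzero = (result.gene_scores.to_numpy() > 0).mean()
        assert 0.02 < frac_nonzero < 0.09

    def test_planted_segment_scores_one_between_bands(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=(100, 50))
        clone = rng.normal(size=(100, 20))
        clone[20:70] += 3.0  # between 2 and k_outer=4 reference SDs
        smoothed = frame(np.hstack([ref, clone]),
                         cells=[f"r{i}" for i in range(50)] + [f"t{i}" for i in range(20)])
        result = score_cnv(smoothed, [f"r{i}" for i in range(50)], k_outer=4)
        seg = result.gene_scores.iloc[20:70, 50:].to_numpy()
        assert (seg >= 1).mean() > 0.8
        off_ref = result.gene_scores.iloc[:, :50].to_numpy()
        assert (off_ref == 0).mean() > 0.9

    def test_identical_matrix_degenerate(self):
        smoothed = frame(np.ones((5, 6)))
        result = score_cnv(smoothed, ["c0", "c1"], k_outer=4)
        assert (result.gene_scores.to_numpy() == 0).all()
        assert not result.malignant.any()

    def test_totals_are_column_sums_and_malignant_rule(self):
        rng = np.random.default_rng(2)
        smoothed = frame(rng.normal(size=(30, 12)))
        result = score_cnv(smoothed, ["c0", "c1", "c2", "c3"], k_outer=3.5)
        np.testing.assert_array_equal(
            result.total.to_numpy(), result.gene_scores.sum(axis=0).to_numpy())
        np.testing.assert_array_equal(
            result.malignant.to_numpy(),
            result.total.to_numpy() > result.total.median())
        assert set(np.unique(result.gene_scores.to_numpy())) <= {0, 1, 2}

    def test_k_outer_must_exceed_two(self):
        smoothed = frame(np.zeros((2, 3)))
        with pytest.raises(ValidationError):
            score_cnv(smoothed, ["c0"], k_outer=2.0)


class TestPipeline:
    def test_scores_invariant_to_per_gene_constant(self):
        expr, anno, pos, _ = gen_single_cell(n_ref=40, n_tumor=40, n_genes=60,
                                             segments=((10, 20, 3.0),), seed=5)
        ref = anno.loc[anno.label == "reference", "cell_id"].tolist()
        base = cnv_pipeline(expr, pos, ref, window=5, median_width=3)
        shifted = expr.add(np.arange(len(expr)) * 0.7, axis=0)
        again = cnv_pipeline(shifted, pos, ref, window=5, median_width=3)
        pd.testing.assert_frame_equal(base.gene_scores, again.gene_scores)

    def test_planted_clone_recovered(self):
        expr, anno, pos, truth = gen_single_cell(
            n_ref=250, n_tumor=250, n_genes=200, segments=((40, 50, 3.0),), seed=0)
        ref = anno.loc[anno.label == "reference", "cell_id"].tolist()
        result = cnv_pipeline(expr, pos, ref)
        clone = np.array([truth.labels["clone"][c] for c in result.cells])
        accuracy = float(np.mean(result.malignant.to_numpy() == clone))
        assert accuracy >= 0.9

    def test_null_clone_near_chance(self):
        expr, anno, pos, truth = gen_single_cell(
            n_ref=100, n_tumor=100, n_genes=100, segments=((10, 20, 0.0),), seed=3)
        ref = anno.loc[anno.label == "reference", "cell_id"].tolist()
        result = cnv_pipeline(expr, pos, ref, window=11)
        clone = np.array([truth.labels["clone"][c] for c in result.cells])
        accuracy = float(np.mean(result.malignant.to_numpy() == clone))
        assert 0.3 < accuracy < 0.7
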