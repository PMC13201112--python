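"""kNN weights, Moran's I, Lee's L, permutation inference, residualization."""

import numpy as np
import pandas as pd
import pytest

from markermeta import (
    ValidationError,
    composite_immune_score,
    knn_weights,
    lees_l,
    morans_i,
    permutation_test,
    residualize,
)


def brute_force_moran(values, w):
    z = values - values.mean()
    n = len(z)
    dense = np.zeros((n, n))
    for i in range(n):
        for j, wij in zip(w.neighbors[i], w.weights[i]):
            dense[i, j] = wij
    num = sum(dense[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / dense.sum()) * num / np.sum(z ** 2)


def brute_force_lee(x, y, w):
    zx, zy = x - x.mean(), y - y.mean()
    n = len(zx)
    dense = np.zeros((n, n))
    for i in range(n):
        for j, wij in zip(w.neighbors[i], w.weights[i]):
            dense[i, j] = wij
    num = sum((dense[i] @ zx) * (dense[i] @ zy) for i in range(n))
    denom = np.sum(dense.sum(axis=1) ** 2)
    return (n / denom) * num / (np.sqrt(np.sum(zx ** 2)) * np.sqrt(np.sum(zy ** 2)))


class TestKnnWeights:
    def test_unit_grid_side_neighbors(self):
        coords = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        w = knn_weights(coords, k=2)
        assert sorted(w.neighbors[0]) == [1, 2]   # not the diagonal spot 3
        assert sorted(w.neighbors[3]) == [1, 2]
        np.testing.assert_allclose(w.weights, 0.5)
        np.testing.assert_allclose(w.weights.sum(axis=1), 1.0)

    def test_collinear_tie_broken_by_index(self):
        coords = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)
        w = knn_weights(coords, k=1)
        assert w.neighbors[1, 0] == 0  # equidistant endpoints -> lower index

    def test_no_self_neighbors(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(size=(30, 2))
        w = knn_weights(coords, k=5)
        for i in range(30):
            assert i not in w.neighbors[i]

    def test_k_out_of_range_rejected(self):
        coords = np.zeros((4, 2))
        with pytest.raises(ValidationError):
            knn_weights(coords, k=4)

    def test_duplicate_coordinates_allowed(self):
        coords = np.array([[0, 0], [0, 0], [1, 1]], dtype=float)
        w = knn_weights(coords, k=1)
        assert w.neighbors[0, 0] == 1
        assert w.neighbors[1, 0] == 0


class TestMoransI:
    def test_gradient_is_positively_autocorrelated(self):
        xs, ys = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        w = knn_weights(coords, k=2)
        assert morans_i(coords[:, 0], w) > 0.5

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(8, 25))
            coords = rng.uniform(size=(n, 2))
            values = rng.normal(size=n)
            w = knn_weights(coords, k=int(rng.integers(1, 5)))
            assert morans_i(values, w) == pytest.approx(
                brute_force_moran(values, w), abs=1e-10)

    def test_permutation_mean_matches_null_expectation(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(size=(60, 2))
        values = rng.normal(size=60)
        w = knn_weights(coords, k=4)
        perms = [morans_i(values[rng.permutation(60)], w) for _ in range(2000)]
        assert np.mean(perms) == pytest.approx(-1 / 59, abs=0.01)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(size=(40, 2))
        values = rng.normal(size=40)
        w = knn_weights(coords, k=3)
        assert morans_i(3.0 * values - 7.0, w) == pytest.approx(morans_i(values, w))

    def test_constant_vector_rejected(self):
        w = knn_weights(np.random.default_rng(0).uniform(size=(10, 2)), k=2)
        with pytest.raises(ValidationError):
            morans_i(np.ones(10), w)


class TestLeesL:
    def test_self_association_of_locally_constant_field_is_one(self):
        # pairs of mutually nearest spots with equal values: lag(z) = z
        coords = np.array([[0, 0], [0.1, 0], [10, 0], [10.1, 0]], dtype=float)
        values = np.array([1.0, 1.0, -1.0, -1.0])
        w = knn_weights(coords, k=1)
        assert lees_l(values, values, w) == pytest.approx(1.0)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(size=(30, 2))
        x = rng.normal(size=30)
        w = knn_weights(coords, k=3)
        assert lees_l(x, -x, w) == pytest.approx(-lees_l(x, x, w))

    def test_symmetric_in_arguments_and_self_nonnegative(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(size=(25, 2))
        x, y = rng.normal(size=25), rng.normal(size=25)
        w = knn_weights(coords, k=4)
        assert lees_l(x, y, w) == pytest.approx(lees_l(y, x, w))
        assert lees_l(x, x, w) >= 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(8, 20))
            coords = rng.uniform(size=(n, 2))
            x, y = rng.normal(size=n), rng.normal(size=n)
            w = knn_weights(coords, k=int(rng.integers(1, 4)))
            assert lees_l(x, y, w) == pytest.approx(
                brute_force_lee(x, y, w), abs=1e-10)

    def test_independent_fields_center_near_zero(self):
        from markermeta import gen_spatial

        spots, _ = gen_spatial(side=12, length_scale=2, seed=7)
        w = knn_weights(spots.coords, k=6)
        x = spots.expr["marker"].to_numpy()
        y = spots.expr["control"].to_numpy()
        r = permutation_test(lees_l, (x, y), w, n_perm=999, seed=0)
        assert abs(r.expectation) < 0.05


class TestPermutationTest:
    def test_minimal_count_formula(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        w = knn_weights(coords, k=2)
        values = np.array([5.0, 1.0, 2.0, 3.0])
        r = permutation_test(morans_i, values, w, n_perm=1, seed=1)
        assert r.p in (0.5, 1.0)

    def test_reproducible_for_fixed_seed(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(size=(50, 2))
        values = rng.normal(size=50)
        w = knn_weights(coords, k=4)
        a = permutation_test(morans_i, values, w, n_perm=99, seed=42)
        b = permutation_test(morans_i, values, w, n_perm=99, seed=42)
        assert a == b

    def test_opposite_tail_saturates_at_one(self):
        # anti-correlated pair tested against the "greater" tail
        coords = np.array([[0, 0], [0.1, 0], [10, 0], [10.1, 0],
                           [20, 0], [20.1, 0], [30, 0], [30.1, 0]], dtype=float)
        x = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        w = knn_weights(coords, k=1)
        r = permutation_test(lees_l, (x, -x), w, n_perm=999, seed=0,
                             alternative="greater")
        assert r.statistic == pytest.approx(-1.0)
        assert r.p == 1.0

    def test_invalid_alternative_rejected(self):
        w = knn_weights(np.random.default_rng(0).uniform(size=(10, 2)), k=2)
        with pytest.raises(ValidationError):
            permutation_test(morans_i, np.arange(10.0), w, alternative="both")


class TestResidualize:
    def test_perfect_fit_gives_zero_residuals(self):
        c = np.arange(20, dtype=float)
        np.testing.assert_allclose(residualize(2 * c + 3, c), 0.0, atol=1e-10)

    def test_orthogonal_values_only_centered(self):
        rng = np.random.default_rng(9)
        c = rng.normal(size=100)
        v = rng.normal(size=100)
        v -= np.polyval(np.polyfit(c, v, 1), c)  # force orthogonality
        out = residualize(v + 5.0, c)
        np.testing.assert_allclose(out, v - v.mean(), atol=1e-10)

    def test_residuals_orthogonal_and_centered(self):
        rng = np.random.default_rng(10)
        c = rng.normal(size=80)
        v = 1.5 * c + rng.normal(size=80)
        out = residualize(v, c)
        assert abs(out.mean()) < 1e-10
        assert abs(np.dot(out, c)) < 1e-8

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError):
            residualize(np.arange(5.0), np.ones(5))


class TestCompositeImmuneScore:
    def test_sum_of_five_fractions(self):
        fr = pd.DataFrame({c: [0.1, 0.0] for c in
                           ("cd8_t", "cd4_t", "b_cell", "nk", "macrophage")})
        np.testing.assert_allclose(composite_immune_score(fr), [0.5, 0.0])

    def test_missing_column_rejected(self):
        fr = pd.DataFrame({"cd8_t": [0.1]})
        with pytest.raises(ValidationError, match="missing"):
            composite_immune_score(fr)

    def test_simplex_fractions_bounded_by_one(self):
        from markermeta import gen_spatial

        spots, _ = gen_spatial(side=8, seed=11)
        score = composite_immune_score(spots.fractions)
        assert np.all(score >= 0) and np.all(score <= 1)
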