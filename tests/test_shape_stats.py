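"""Shape PCA, two-block PLS, RV coefficient, allometry, group variance."""

import numpy as np
import pytest

from dentomorph.gpa import generalized_procrustes
from dentomorph.shape_stats import (
    group_shape_variance,
    pc_warp_endpoints,
    rv_coefficient,
    shape_pca,
    size_shape_regression,
    two_block_pls,
)


class TestPCA:
    def test_variance_fractions_sum_to_100(self, rng):
        p = shape_pca(rng.normal(size=(20, 30)))
        assert p.variance_fractions.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(p.eigenvalues) <= 1e-12)
        assert (p.eigenvalues > 0).sum() <= min(19, 30)

    def test_planted_single_axis_dominates(self, rng):
        """One planted shape axis: PC1 captures it and almost all variance."""
        axis = rng.normal(size=60)
        axis /= np.linalg.norm(axis)
        scores = rng.normal(size=(100, 1))
        x = scores * axis + rng.normal(scale=0.01, size=(100, 60))
        p = shape_pca(x)
        assert p.variance_fractions[0] >= 95.0
        assert abs(p.eigenvectors[:, 0] @ axis) >= 0.99

    def test_scores_covariance_is_diagonal_eigenvalues(self, rng):
        x = rng.normal(size=(15, 12))
        p = shape_pca(x)
        cov = p.scores.T @ p.scores / (len(x) - 1)
        np.testing.assert_allclose(cov, np.diag(p.eigenvalues), atol=1e-9)

    def test_full_reconstruction(self, rng):
        x = rng.normal(size=(10, 8))
        p = shape_pca(x)
        rebuilt = p.mean_ + p.scores @ p.eigenvectors.T
        np.testing.assert_allclose(rebuilt, x, atol=1e-9)

    def test_too_few_specimens_rejected(self, rng):
        with pytest.raises(ValueError):
            shape_pca(rng.normal(size=(2, 6)))


class TestWarpEndpoints:
    def _pca(self, small_cohort):
        res = generalized_procrustes(small_cohort, tol=1e-12)
        return shape_pca(res.tangent_coords, consensus=res.consensus)

    def test_zero_score_is_consensus(self, small_cohort):
        p = self._pca(small_cohort)
        minus, plus, model = pc_warp_endpoints(p, 0, 0.0, range_check=False)
        np.testing.assert_allclose(plus, p.consensus, atol=1e-12)
        np.testing.assert_allclose(minus, p.consensus, atol=1e-12)

    def test_endpoints_reflect_through_consensus(self, small_cohort):
        p = self._pca(small_cohort)
        minus, plus, model = pc_warp_endpoints(p, 1, 0.05, range_check=False)
        np.testing.assert_allclose(
            plus - p.consensus, -(minus - p.consensus), atol=1e-12
        )
        assert model is not None

    def test_endpoint_projects_back_to_its_score(self, small_cohort):
        p = self._pca(small_cohort)
        s = 0.04
        _, plus, _ = pc_warp_endpoints(p, 0, s, range_check=False)
        score = (plus.ravel() - p.mean_) @ p.eigenvectors[:, 0]
        assert score == pytest.approx(s, abs=1e-9)

    def test_out_of_range_pc_rejected(self, small_cohort):
        p = self._pca(small_cohort)
        with pytest.raises(IndexError):
            pc_warp_endpoints(p, 99, 0.1)

    def test_range_check_guards_extreme_scores(self, small_cohort):
        p = self._pca(small_cohort)
        with pytest.raises(ValueError, match="3x"):
            pc_warp_endpoints(p, 0, 1e3)


class TestPLS:
    def test_self_covariation(self, rng):
        x = rng.normal(size=(25, 10))
        res = two_block_pls(x, x.copy())
        assert res.pairwise_correlations[0] == pytest.approx(1.0, abs=1e-9)
        # SW shares equal the squared-eigenvalue shares of the PCA
        p = shape_pca(x)
        expected = 100.0 * p.eigenvalues**2 / np.sum(p.eigenvalues**2)
        np.testing.assert_allclose(
            res.pct_total_squared_covariance[: len(expected)], expected, atol=1e-8
        )

    def test_block_order_symmetry(self, rng):
        x = rng.normal(size=(20, 8))
        y = 0.5 * x[:, :6] + rng.normal(size=(20, 6))
        a = two_block_pls(x, y)
        b = two_block_pls(y, x)
        np.testing.assert_allclose(a.singular_values, b.singular_values, atol=1e-10)
        np.testing.assert_allclose(
            np.abs(a.pairwise_correlations), np.abs(b.pairwise_correlations), atol=1e-10
        )
        assert a.rv_coefficient == pytest.approx(b.rv_coefficient, abs=1e-12)

    def test_pct_sums_to_100(self, rng):
        res = two_block_pls(rng.normal(size=(15, 7)), rng.normal(size=(15, 9)))
        assert res.pct_total_squared_covariance.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.abs(res.pairwise_correlations) <= 1.0 + 1e-12)

    def test_unpaired_blocks_rejected(self, rng):
        with pytest.raises(ValueError, match="unpaired"):
            two_block_pls(rng.normal(size=(10, 4)), rng.normal(size=(11, 4)))

    def test_planted_latent_factor_recovered(self, rng):
        """X and Y share one latent factor; r1 estimates the planted 0.8."""
        n, p, q = 200, 40, 30
        ax = rng.normal(size=p)
        ax /= np.linalg.norm(ax)
        ay = rng.normal(size=q)
        ay /= np.linalg.norm(ay)
        sd = 0.5
        a = sd * np.sqrt(0.8 / 0.2)
        u = rng.normal(size=(n, 1))
        x = a * u * ax + rng.normal(scale=sd, size=(n, p))
        y = a * u * ay + rng.normal(scale=sd, size=(n, q))
        res = two_block_pls(x, y)
        assert res.pairwise_correlations[0] == pytest.approx(0.8, abs=0.1)


class TestRV:
    def test_self_and_scaled(self, rng):
        x = rng.normal(size=(12, 5))
        assert rv_coefficient(x, x) == pytest.approx(1.0, abs=1e-12)
        assert rv_coefficient(x, -3.7 * x) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_invariance(self, rng):
        x = rng.normal(size=(14, 6))
        q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        assert rv_coefficient(x, x @ q) == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_toy_blocks(self):
        x = np.array([[1.0, 0.0, 2.0], [2.0, 1.0, 0.0], [0.0, 2.0, 1.0], [1.0, 1.0, 1.0]])
        y = np.array([[0.5, 1.0, 0.0], [1.5, 0.0, 1.0], [0.0, 0.5, 2.0], [1.0, 1.0, 1.0]])
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        sxx = xc.T @ xc / 3
        syy = yc.T @ yc / 3
        sxy = xc.T @ yc / 3
        oracle = np.trace(sxy @ sxy.T) / np.sqrt(
            np.trace(sxx @ sxx) * np.trace(syy @ syy)
        )
        assert rv_coefficient(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_block_rejected(self, rng):
        with pytest.raises(ValueError):
            rv_coefficient(rng.normal(size=(8, 3)), np.ones((8, 3)))


class TestRegression:
    def test_exact_linear_shapes_give_100pct(self, rng):
        g = rng.normal(size=30)
        v = rng.normal(size=12)
        x = np.outer(g, v) + rng.normal(size=12)  # consensus + lnCS * v
        res = size_shape_regression(x, g)
        assert res.pct_variance_explained == pytest.approx(100.0, abs=1e-9)
        np.testing.assert_allclose(res.predict(g), x, atol=1e-9)

    def test_coefficients_match_coordinatewise_ols(self, rng):
        x = rng.normal(size=(25, 9))
        g = rng.normal(size=25)
        res = size_shape_regression(x, g)
        for j in range(9):
            slope = np.polyfit(g, x[:, j], 1)[0]
            assert res.coefficients[j] == pytest.approx(slope, abs=1e-10)

    def test_permuted_lncs_explains_little(self, rng):
        """Breaking the size-shape link leaves only chance-level signal."""
        g = rng.normal(size=100)
        v = rng.normal(size=40)
        v /= np.linalg.norm(v)
        x = 0.5 * np.outer(g, v) + rng.normal(scale=0.3, size=(100, 40))
        real = size_shape_regression(x, g).pct_variance_explained
        null = [
            size_shape_regression(x, rng.permutation(g)).pct_variance_explained
            for _ in range(99)
        ]
        assert real > np.percentile(null, 95)

    def test_constant_lncs_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            size_shape_regression(rng.normal(size=(10, 4)), np.ones(10))


class TestGroupVariance:
    def test_identical_shapes_zero(self):
        x = np.tile(np.arange(6.0), (4, 1))
        out = group_shape_variance(x, ["a"] * 4)
        assert out["a"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_algebra(self):
        x = np.zeros((2, 3))
        x[1, 0] = 2.0  # tangent distance d = 2
        out = group_shape_variance(x, ["g", "g"])
        assert out["g"] == pytest.approx(2.0**2 / 2, abs=1e-12)

    def test_isotropic_noise_expectation(self, rng):
        """Variance of isotropic noise approaches D * sigma^2."""
        d, sigma, n = 20, 0.3, 500
        x = rng.normal(scale=sigma, size=(n, d))
        out = group_shape_variance(x, ["g"] * n)
        assert out["g"] == pytest.approx(d * sigma**2, rel=0.10)

    def test_singleton_group_excluded_with_warning(self, rng):
        x = rng.normal(size=(5, 4))
        with pytest.warns(UserWarning, match="excluded"):
            out = group_shape_variance(x, ["a", "a", "a", "a", "b"])
        assert set(out) == {"a"}
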