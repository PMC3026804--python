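import numpy as np
import pytest
from scipy import stats

from pollnet.diversity import (
    bray_curtis,
    dissimilarity_matrix,
    fit_sar_mix,
    hurlbert_pie,
    morisita_horn,
    one_way_anova,
    partial_mantel,
    residualize,
    spatial_weights,
)

from oracles import anova_oracle


def rand_dist(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return m


class TestHurlbertPie:
    def test_single_species_zero(self):
        assert hurlbert_pie([17]) == pytest.approx(0.0)

    def test_two_equal_counts(self):
        assert hurlbert_pie([10, 10]) == pytest.approx((20 / 19) * 0.5)

    def test_many_equal_species_approaches_one(self):
        assert hurlbert_pie([5] * 200) > 0.99

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            hurlbert_pie([1])


class TestDissimilarities:
    def test_identical_vectors_zero(self):
        x = [3, 1, 4]
        assert bray_curtis(x, x) == pytest.approx(0.0)
        assert morisita_horn(x, x) == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        assert bray_curtis([2, 0], [0, 3]) == pytest.approx(1.0)
        assert morisita_horn([2, 0], [0, 3]) == pytest.approx(1.0)

    def test_bray_curtis_hand_case(self):
        assert bray_curtis([2, 0], [1, 1]) == pytest.approx(0.5)

    def test_matrix_properties(self, rng):
        counts = rng.integers(0, 20, size=(6, 8)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1
        for method in ("bray_curtis", "morisita_horn"):
            d = dissimilarity_matrix(counts, method)
            np.testing.assert_allclose(d, d.T)
            np.testing.assert_allclose(np.diagonal(d), 0)
            assert (d >= -1e-12).all() and (d <= 1 + 1e-12).all()

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])


class TestResidualize:
    def test_orthogonal_covariate_returns_centred(self, rng):
        y = np.array([1.0, 3.0, 2.0, 4.0])
        x = np.array([1.0, -1.0, 1.0, -1.0])  # orthogonal to y - mean(y)?
        # construct orthogonality explicitly
        y = y - (y @ x) / (x @ x) * x
        res = residualize(y, x)
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_perfect_linear_relation_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = residualize(2 * x, x)
        np.testing.assert_allclose(res, 0, atol=1e-12)

    def test_normal_equation_fixture(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 1.5, 3.5, 3.0])
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(residualize(y, x), y - X @ beta, atol=1e-12)

    def test_mean_zero(self, rng):
        res = residualize(rng.normal(size=10), rng.normal(size=10))
        assert res.mean() == pytest.approx(0.0, abs=1e-12)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            residualize([1.0, 2.0], [0.0, 1.0])


class TestSpatialWeights:
    def test_two_equidistant_neighbours(self):
        coords = [[0, 0], [1, 0], [-1, 0]]
        sw = spatial_weights(coords)
        np.testing.assert_allclose(sw.W[0], [0, 0.5, 0.5])

    def test_duplicate_coordinates_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            spatial_weights([[0, 0], [0, 0], [1, 1]])

    def test_rows_sum_to_one(self, rng):
        sw = spatial_weights(rng.uniform(0, 10, size=(8, 2)))
        np.testing.assert_allclose(sw.W.sum(axis=1), 1.0)

    def test_knn_scheme(self, rng):
        sw = spatial_weights(rng.uniform(0, 10, size=(10, 2)), scheme="knn",
                             k=3, row_standardize=False)
        assert (sw.W.sum(axis=1) == 3).all()

    def test_gabriel_connected(self, rng):
        sw = spatial_weights(rng.uniform(0, 10, size=(12, 2)), scheme="gabriel",
                             row_standardize=False)
        assert (sw.W.sum(axis=1) >= 1).all()


class TestSarMix:
    def test_rho_zero_matches_ols(self, rng):
        n = 30
        coords = rng.uniform(0, 10, size=(n, 2))
        sw = spatial_weights(coords)
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, size=n)
        fit = fit_sar_mix(y, x[:, None], sw, predictor_names=["x"],
                          lag_predictors=False, fix_rho=0.0)
        X = np.column_stack([np.ones(n), x])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.intercept == pytest.approx(ols[0], abs=1e-6)
        assert fit.beta[0] == pytest.approx(ols[1], abs=1e-6)

    def test_gamma_null_recovery(self):
        # data with gamma = 0: lagged-predictor slope centred on zero
        ests = []
        for s in range(30):
            r = np.random.default_rng(s)
            n = 40
            sw = spatial_weights(r.uniform(0, 10, size=(n, 2)), scheme="gabriel")
            x = r.normal(size=n)
            y = 1.0 + x + r.normal(0, 1, size=n)
            fit = fit_sar_mix(y, x[:, None], sw, predictor_names=["x"])
            ests.append(fit.gamma[0])
        assert abs(np.mean(ests)) < 0.15

    def test_profile_is_local_max(self, rng):
        from pollnet.diversity import _sar_loglik

        n = 40
        sw = spatial_weights(rng.uniform(0, 10, size=(n, 2)), scheme="gabriel")
        x = rng.normal(size=n)
        y = np.linalg.solve(np.eye(n) - 0.3 * sw.W, 1 + x + rng.normal(size=n))
        fit = fit_sar_mix(y, x[:, None], sw, predictor_names=["x"])
        Z = np.column_stack([np.ones(n), x, sw.W @ x])
        ev = np.linalg.eigvals(sw.W)
        ll_hat = _sar_loglik(fit.rho, y, Z, sw.W, ev)[0]
        for dr in (-0.01, 0.01):
            assert ll_hat >= _sar_loglik(fit.rho + dr, y, Z, sw.W, ev)[0] - 1e-9

    def test_collinear_design_rejected(self, rng):
        n = 20
        sw = spatial_weights(rng.uniform(0, 10, size=(n, 2)))
        x = rng.normal(size=n)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_sar_mix(rng.normal(size=n), X, sw, lag_predictors=False)

    def test_small_sample_warning(self, rng):
        n = 8
        sw = spatial_weights(rng.uniform(0, 10, size=(n, 2)))
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        with pytest.warns(UserWarning, match="fragile"):
            fit_sar_mix(y, x[:, None], sw, lag_predictors=False)


class TestPartialMantel:
    def test_b_equals_a(self, rng):
        A = rand_dist(rng, 12)
        C = rand_dist(rng, 12)
        res = partial_mantel(A, A, C, permutations=200, seed=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-9)
        assert res.p_value <= 0.05

    def test_a_equals_c_partials_out(self, rng):
        A = rand_dist(rng, 12)
        B = rand_dist(rng, 12)
        res = partial_mantel(A, B, A, permutations=100, seed=0)
        assert abs(res.statistic) < 1e-6

    def test_requires_four_objects(self, rng):
        A = rand_dist(rng, 3)
        with pytest.raises(ValueError):
            partial_mantel(A, A, A)

    def test_asymmetric_rejected(self, rng):
        A = rng.random((5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            partial_mantel(A, rand_dist(rng, 5), rand_dist(rng, 5))

    def test_seed_reproducibility(self, rng):
        A, B, C = (rand_dist(rng, 10) for _ in range(3))
        r1 = partial_mantel(A, B, C, permutations=100, seed=4)
        r2 = partial_mantel(A, B, C, permutations=100, seed=4)
        assert r1.p_value == r2.p_value

    def test_pearson_method(self, rng):
        A, B, C = (rand_dist(rng, 10) for _ in range(3))
        res = partial_mantel(A, B, C, method="pearson", permutations=100, seed=1)
        assert -1 <= res.statistic <= 1


class TestAnova:
    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            one_way_anova([1.0, 1.0, 2.0, 2.0], ["a", "a", "b", "b"])

    def test_hand_case_f8(self):
        out = one_way_anova([1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"])
        assert out["F"] == pytest.approx(8.0)
        assert (out["df1"], out["df2"]) == (1, 2)
        assert out["p_value"] == pytest.approx(float(stats.f.sf(8.0, 1, 2)))

    def test_five_groups_matches_oracle(self, rng):
        vals = rng.normal(size=25)
        labels = np.repeat(list("abcde"), 5)
        out = one_way_anova(vals, labels)
        f, df1, df2 = anova_oracle(vals, labels)
        assert out["F"] == pytest.approx(f)
        assert (out["df1"], out["df2"]) == (df1, df2)
        # cross-check with scipy
        f2, p2 = stats.f_oneway(*(vals[labels == g] for g in "abcde"))
        assert out["F"] == pytest.approx(float(f2))
        assert out["p_value"] == pytest.approx(float(p2))

    def test_one_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([1.0, 2.0], ["a", "a"])
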