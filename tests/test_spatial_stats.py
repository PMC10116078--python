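import numpy as np
import pandas as pd
import pytest
from scipy import stats

from betascape.spatial_stats import (
    SpatialWeights,
    build_weights,
    fit_gamma_glm,
    fit_log_sar_error,
    fit_ols,
    fit_sar_error,
    moran_test,
    morans_i,
    select_and_fit,
    vif,
)


def grid_weights(n, k=8, seed=None):
    side = int(np.ceil(np.sqrt(n)))
    xy = np.array([[i % side, i // side] for i in range(n)], dtype=float)
    if seed is not None:  # jitter to break ties on larger grids
        xy += np.random.default_rng(seed).uniform(-0.01, 0.01, xy.shape)
    return build_weights(xy, k=k)


def moran_brute(x, w):
    """Textbook double-loop Moran's I."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / w.sum() * num / (z @ z)


class TestBuildWeights:
    def test_two_by_two_nearest(self):
        coords = pd.DataFrame({"x": [0, 1, 0, 1.2], "y": [0, 0, 1, 1]},
                              index=list("abcd"))
        w = build_weights(coords, k=1, row_standardize=False)
        # union symmetrization: a-b (dist 1) and a-c (dist 1) tie is broken
        # by unit order, so a's single nearest neighbour is b
        assert w.binary[0, 1] == 1
        assert w.w.sum() >= 3

    def test_row_standardized_rows_sum_to_one(self):
        w = grid_weights(30, k=4)
        assert np.allclose(w.w.sum(axis=1), 1.0)
        assert np.all(np.diag(w.w) == 0)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k must"):
            grid_weights(9, k=9)

    def test_self_neighbor_rejected(self):
        with pytest.raises(ValueError, match="self-neighbors"):
            SpatialWeights(["a", "b"], np.array([[0.5, 0.5], [1.0, 0.0]]), True)


class TestVif:
    def test_orthogonal_predictors_unity(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        out = vif(np.column_stack([x1, x2]))
        assert np.allclose(out, 1.0)

    def test_near_collinear_flagged(self):
        rng = np.random.default_rng(0)
        x1 = rng.standard_normal(200)
        x2 = x1 + 1e-3 * rng.standard_normal(200)
        out = vif(np.column_stack([x1, x2, rng.standard_normal(200)]))
        assert out.iloc[0] > 3 and out.iloc[1] > 3

    def test_matches_bruteforce_r2(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((500, 3))
        # three predictors with built-in pairwise correlation
        common = rng.standard_normal(500)
        X = z + common[:, None]
        out = vif(X)
        for j in range(3):
            others = np.column_stack([np.ones(500), np.delete(X, j, axis=1)])
            beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
            resid = X[:, j] - others @ beta
            r2 = 1 - resid.var() / X[:, j].var()
            assert out.iloc[j] == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_perfect_collinearity_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="collinear"):
            vif(np.column_stack([x, 2 * x, np.random.default_rng(2).random(20)]))


class TestOls:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 2))
        y = 1.0 + X @ [2.0, -1.0]
        res = fit_ols(y, X)
        assert np.abs(res.resid).max() < 1e-10
        assert res.params.to_numpy() == pytest.approx([1.0, 2.0, -1.0], abs=1e-10)

    def test_simulation_recovery(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(500)
        y = 2.0 + 0.5 * x + rng.standard_normal(500)
        res = fit_ols(y, x)
        assert abs(res.params["Intercept"] - 2.0) < 3 * res.bse["Intercept"]
        assert abs(res.params["x1"] - 0.5) < 3 * res.bse["x1"]

    def test_intercept_only_is_mean(self):
        y = np.array([1.0, 2.0, 6.0, 7.0])
        res = fit_ols(y)
        assert res.params["Intercept"] == pytest.approx(y.mean())

    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError, match="rank"):
            fit_ols(np.arange(10.0), X)


class TestGammaGlm:
    def test_simulation_recovery(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(1000)
        mu = 10.0 + 0.2 * x
        y = rng.gamma(shape=5.0, scale=mu / 5.0)
        res = fit_gamma_glm(y, x)
        assert res.family == "gamma-identity-glm"
        assert abs(res.params["Intercept"] - 10.0) < 3 * res.bse["Intercept"]
        assert abs(res.params["x1"] - 0.2) < 3 * res.bse["x1"]

    def test_zero_response_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            fit_gamma_glm(np.array([1.0, 0.0, 2.0]), np.arange(3.0))

    def test_constant_mean_intercept(self):
        rng = np.random.default_rng(6)
        y = rng.gamma(shape=5.0, scale=2.0, size=800)
        res = fit_gamma_glm(y)
        assert res.params["Intercept"] == pytest.approx(y.mean(), rel=0.05)


class TestMoran:
    def test_checkerboard_is_minus_one(self):
        coords = pd.DataFrame({"x": [0, 1, 0, 1], "y": [0, 0, 1, 1]},
                              index=list("abcd"))
        w = build_weights(coords, k=2)  # == rook on the 2x2 grid
        assert morans_i(np.array([1.0, -1.0, -1.0, 1.0]), w) == pytest.approx(-1.0)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(8, 31))
            w = grid_weights(n, k=3, seed=int(rng.integers(1000)))
            x = rng.standard_normal(n)
            assert morans_i(x, w) == pytest.approx(moran_brute(x, w.w), abs=1e-12)

    def test_constant_vector_rejected(self):
        w = grid_weights(16, k=3)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(16), w)

    def test_zero_weights_rejected(self):
        w = SpatialWeights(list(range(4)), np.zeros((4, 4)), False)
        with pytest.raises(ValueError, match="zero"):
            morans_i(np.arange(4.0), w)

    def test_pvalue_scale_invariant(self):
        rng = np.random.default_rng(8)
        w = grid_weights(49, k=4)
        x = rng.standard_normal(49)
        _, p1 = moran_test(x, w, n_perm=99, seed=5)
        _, p2 = moran_test(1234.5 * x, w, n_perm=99, seed=5)
        assert p1 == p2

    def test_detects_strong_autocorrelation(self):
        w = grid_weights(100, k=4)
        side = 10
        smooth = np.array([i % side + i // side for i in range(100)], float)
        i_obs, p = moran_test(smooth, w, n_perm=199, seed=0)
        assert i_obs > 0.5 and p < 0.01


class TestSarError:
    def test_lambda_zero_matches_ols(self):
        rng = np.random.default_rng(9)
        w = grid_weights(100, k=6)
        X = rng.standard_normal((100, 2))
        y = 1.0 + X @ [0.5, -0.3] + rng.standard_normal(100)
        r_ols = fit_ols(y, X)
        r_sar = fit_sar_error(y, X, w, force_lambda=0.0)
        assert abs(r_ols.llf - r_sar.llf) < 1e-8
        assert np.allclose(r_ols.params, r_sar.params, atol=1e-6)

    def test_parameter_recovery_small(self):
        rng = np.random.default_rng(10)
        n, lam_true, beta = 300, 0.6, np.array([1.0, 0.5, -0.3])
        w = grid_weights(n, k=8)
        a_inv = np.linalg.inv(np.eye(n) - lam_true * w.w)
        lams, betas = [], []
        for _ in range(20):
            X = rng.standard_normal((n, 2))
            y = beta[0] + X @ beta[1:] + a_inv @ rng.standard_normal(n)
            res = fit_sar_error(y, X, w)
            lams.append(res.lam)
            betas.append(res.params.to_numpy())
        assert abs(np.mean(lams) - lam_true) < 0.1
        assert np.abs(np.mean(betas, axis=0) - beta).max() < 0.1

    def test_whitened_residuals_lose_autocorrelation(self):
        rng = np.random.default_rng(11)
        n, lam_true = 225, 0.7
        w = grid_weights(n, k=8)
        a_inv = np.linalg.inv(np.eye(n) - lam_true * w.w)
        X = rng.standard_normal((n, 2))
        y = 1.0 + X @ [0.5, -0.3] + a_inv @ rng.standard_normal(n)
        res = fit_sar_error(y, X, w)
        _, p_innov = moran_test(res.resid, w, n_perm=199, seed=1)
        _, p_struct = moran_test(res.extra["structured_resid"], w, n_perm=199, seed=1)
        assert p_struct < 0.05 < p_innov

    def test_log_variant_backtransform_and_flag(self):
        rng = np.random.default_rng(12)
        n = 225
        w = grid_weights(n, k=8)
        a_inv = np.linalg.inv(np.eye(n) - 0.5 * w.w)
        X = rng.standard_normal((n, 1))
        y = np.exp(1.0 + 0.4 * X[:, 0] + 0.3 * (a_inv @ rng.standard_normal(n)))
        res = fit_log_sar_error(y, X, w)
        assert res.transform == "log-with-back-transform"
        assert (res.fitted_response > 0).all()
        assert abs(res.params["x1"] - 0.4) < 4 * res.bse["x1"]
        with pytest.raises(ValueError, match="positive"):
            fit_log_sar_error(-y, X, w)


class TestSelectAndFit:
    @staticmethod
    def _setup(seed, n=150):
        rng = np.random.default_rng(seed)
        w = grid_weights(n, k=8)
        X = rng.standard_normal((n, 2))
        return rng, w, X

    def test_gaussian_independent_chooses_ols(self):
        rng, w, X = self._setup(13)
        y = 5.0 + X @ [0.5, -0.3] + rng.standard_normal(len(X))
        res = select_and_fit(y, X, w, seed=0, n_perm=199)
        assert res.branch == "ols"
        assert res.vif is not None and (res.vif < 3).all()

    def test_skewed_positive_chooses_gamma(self):
        rng, w, X = self._setup(14)
        mu = 10.0 + X @ [0.5, -0.3]
        y = rng.gamma(shape=2.0, scale=mu / 2.0)
        res = select_and_fit(y, X, w, seed=0, n_perm=199)
        assert res.branch == "gamma-glm"

    def test_spatial_structure_chooses_sar(self):
        rng, w, X = self._setup(15)
        a_inv = np.linalg.inv(np.eye(w.n) - 0.7 * w.w)
        y = 5.0 + X @ [0.5, -0.3] + a_inv @ rng.standard_normal(w.n)
        res = select_and_fit(y, X, w, seed=0, n_perm=199)
        assert res.branch == "sar-error"
        assert res.moran_p is not None

    def test_summary_mentions_branch_and_diagnostics(self):
        rng, w, X = self._setup(16)
        y = 5.0 + X @ [0.5, -0.3] + rng.standard_normal(len(X))
        text = select_and_fit(y, X, w, seed=0, n_perm=199).summary()
        assert "branch" in text and "Moran" in text and "VIF" in text
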