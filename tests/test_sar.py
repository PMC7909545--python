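import numpy as np
import pandas as pd
import pytest

from phyloendemix.sar import (
    fit_sar_error,
    knn_weights,
    moran_correlogram,
    select_sar,
    standardize,
    vif_screen,
)
from phyloendemix.synthetic import SyntheticScenario, simulate_sar_surface


class TestVifScreen:
    def test_identical_columns_leave_one(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(200)
        X = pd.DataFrame({"a": a, "b": a.copy(),
                          "c": rng.standard_normal(200)})
        kept = vif_screen(X)
        assert "c" in kept and len([k for k in kept if k in ("a", "b")]) == 1

    def test_orthogonal_columns_all_survive(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((300, 5)),
                         columns=list("abcde"))
        assert vif_screen(X) == list("abcde")

    def test_constant_column_raises(self):
        X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
        with pytest.raises(ValueError, match="a"):
            vif_screen(X)

    def test_survivors_keep_input_order(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal((250, 3))
        X = pd.DataFrame({"z": base[:, 0], "a": base[:, 1],
                          "m": base[:, 2],
                          "zdup": base[:, 0] + 0.01 * rng.standard_normal(250)})
        kept = vif_screen(X)
        assert kept == [c for c in X.columns if c in kept]


class TestKnnWeights:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        W = knn_weights(rng.random((40, 2)), 5)
        np.testing.assert_allclose(W.sum(axis=1), 1.0)

    def test_symmetrization_by_union(self):
        # 3 collinear points: the middle one gains both ends
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        W = knn_weights(coords, 1)
        assert W[1, 0] > 0 and W[1, 2] > 0
        assert W[0, 1] == 1.0 and W[2, 1] == 1.0

    def test_regular_grid_k4_matches_rook(self):
        xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
        coords = np.column_stack([xs.ravel(), ys.ravel()])
        W = knn_weights(coords, 4)
        i = 5 * 10 + 5  # interior cell
        neigh = np.nonzero(W[i])[0]
        expected = {i - 1, i + 1, i - 10, i + 10}
        assert set(neigh.tolist()) == expected

    def test_duplicate_coordinates_rejected(self):
        with pytest.raises(ValueError):
            knn_weights(np.array([[0.0, 0], [0.0, 0], [1, 1]]), 1)


class TestSarFit:
    def test_lambda_fixed_zero_reproduces_ols(self):
        rng = np.random.default_rng(3)
        n = 120
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        y = 1.0 + 2.0 * X["a"].to_numpy() - X["b"].to_numpy() \
            + rng.standard_normal(n)
        W = knn_weights(rng.random((n, 2)), 4)
        fit = fit_sar_error(y, X, W, lam=0.0)
        Xm = np.column_stack([np.ones(n), X.to_numpy()])
        ols = np.linalg.lstsq(Xm, y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, ols, atol=1e-10)
        assert fit.lam == 0.0

    def test_independent_errors_estimate_near_zero_and_ols(self):
        sc = SyntheticScenario(seed=9, n_rows=15, n_cols=15, sar_lambda=0.0)
        y, X, _ = simulate_sar_surface(sc)
        W = knn_weights(sc.grid.centroids(), 4)
        fit = fit_sar_error(y, standardize(X), W)
        assert abs(fit.lam) < 0.25

    def test_noiseless_response_maximal_fit(self):
        rng = np.random.default_rng(4)
        n = 100
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        y = X.to_numpy() @ np.array([1.0, -0.5])
        W = knn_weights(rng.random((n, 2)), 3)
        fit = fit_sar_error(y, X, W)
        np.testing.assert_allclose(fit.beta[1:], [1.0, -0.5], atol=1e-6)
        assert fit.gr2 > 0.999

    def test_gr2_zero_for_intercept_only_model(self):
        rng = np.random.default_rng(5)
        n = 80
        y = rng.standard_normal(n)
        X = pd.DataFrame(index=range(n))  # no predictors
        W = knn_weights(rng.random((n, 2)), 3)
        fit = fit_sar_error(y, X, W, lam=0.0)
        assert fit.gr2 == pytest.approx(0.0, abs=1e-9)

    def test_aicc_exceeds_aic_and_converges(self):
        rng = np.random.default_rng(6)
        for n in (60, 600):
            X = pd.DataFrame({"a": rng.standard_normal(n)})
            y = X["a"].to_numpy() + rng.standard_normal(n)
            W = knn_weights(rng.random((n, 2)), 3)
            fit = fit_sar_error(y, X, W, lam=0.0)
            q = 2 + 2  # intercept + slope + lambda + sigma^2
            aic = -2 * fit.loglik + 2 * q
            assert fit.aicc > aic
            if n == 600:
                assert fit.aicc - aic < 0.15

    def test_near_singular_design_raises(self):
        rng = np.random.default_rng(7)
        n = 50
        a = rng.standard_normal(n)
        X = pd.DataFrame({"a": a, "b": a})
        W = knn_weights(rng.random((n, 2)), 3)
        with pytest.raises(ValueError):
            fit_sar_error(a, X, W)


class TestSelectSar:
    def test_single_candidate_returned(self):
        sc = SyntheticScenario(seed=2, n_rows=10, n_cols=10)
        y, X, _ = simulate_sar_surface(sc)
        fit = select_sar(y, standardize(X), sc.grid.centroids(), [3])
        assert fit.k == 3

    def test_duplicate_k_tie_keeps_first(self):
        sc = SyntheticScenario(seed=2, n_rows=10, n_cols=10)
        y, X, _ = simulate_sar_surface(sc)
        fit = select_sar(y, standardize(X), sc.grid.centroids(), [4, 4])
        assert fit.k == 4

    def test_rook_dependence_prefers_k_near_four(self):
        hits = 0
        for seed in range(12):
            sc = SyntheticScenario(seed=seed, n_rows=12, n_cols=12,
                                   sar_lambda=0.7)
            y, X, _ = simulate_sar_surface(sc)
            fit = select_sar(y, standardize(X), sc.grid.centroids(),
                             [1, 2, 3, 4, 5, 6])
            hits += fit.k in (3, 4, 5)
        assert hits >= 6  # far above the 1/2 chance level


class TestMoranCorrelogram:
    def test_independent_residuals_near_expectation(self):
        rng = np.random.default_rng(8)
        n = 200
        coords = rng.random((n, 2))
        out = moran_correlogram(rng.standard_normal(n), coords, n_classes=4)
        expected = -1.0 / (n - 1)
        assert np.nanmax(np.abs(out["morans_i"].to_numpy() - expected)) < 0.15

    def test_autocorrelated_field_decays_with_distance(self):
        sc = SyntheticScenario(seed=3, n_rows=15, n_cols=15, sar_lambda=0.85)
        y, X, _ = simulate_sar_surface(sc)
        resid = y - X.to_numpy() @ np.array(sc.sar_beta)
        out = moran_correlogram(resid, sc.grid.centroids(), n_classes=8)
        vals = out["morans_i"].to_numpy()
        assert vals[0] > vals[-1]
        assert vals[0] > 0.2

    def test_single_class_is_global_moran(self):
        rng = np.random.default_rng(9)
        n = 50
        coords = rng.random((n, 2))
        z = rng.standard_normal(n)
        out = moran_correlogram(z, coords, n_classes=1)
        zz = z - z.mean()
        W = (np.ones((n, n)) - np.eye(n))
        manual = n / W.sum() * (zz @ W @ zz) / (zz @ zz)
        assert out["morans_i"].iloc[0] == pytest.approx(manual, abs=1e-12)

    def test_constant_residuals_raise(self):
        with pytest.raises(ValueError):
            moran_correlogram(np.ones(10), np.random.default_rng(0).random((10, 2)))
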