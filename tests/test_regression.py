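"""MLR/PLSR calibration and the R²/RMSE metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spadspec import (
    MLRCalibration,
    PLSCalibration,
    mlr_fit,
    plsr_fit,
    predict,
    score,
    serialize_model,
)


def normal_equations(X, y):
    """Independent OLS oracle: beta = (A'A)^-1 A'y with intercept."""
    A = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(A.T @ A, A.T @ y)


class TestMLR:
    def test_exact_line_through_origin(self):
        model = mlr_fit(np.array([[1.0], [2.0], [3.0]]), np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(model.coef_, [2.0], atol=1e-12)
        assert abs(model.intercept_) < 1e-12

    def test_constant_response(self, rng):
        X = rng.normal(size=(10, 3))
        model = mlr_fit(X, np.full(10, 7.5))
        np.testing.assert_allclose(model.coef_, 0.0, atol=1e-10)
        np.testing.assert_allclose(model.intercept_, 7.5, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = r.normal(size=(30, 5))
            y = r.normal(size=30)
            model = mlr_fit(X, y)
            beta = normal_equations(X, y)
            np.testing.assert_allclose(model.intercept_, beta[0], atol=1e-8)
            np.testing.assert_allclose(model.coef_, beta[1:], atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(40, 6))
        y = rng.normal(size=40)
        model = mlr_fit(X, y)
        res = y - model.predict(X)
        np.testing.assert_allclose(X.T @ res, 0.0, atol=1e-8)
        np.testing.assert_allclose(res.mean(), 0.0, atol=1e-10)

    def test_rank_deficiency_names_bands(self, rng):
        X = rng.normal(size=(20, 3))
        X = np.column_stack([X, X[:, 0]])  # duplicate band
        with pytest.raises(ValueError, match="collinear"):
            mlr_fit(X, rng.normal(size=20), band_indices=[500, 550, 680, 720])

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError, match="samples"):
            mlr_fit(rng.normal(size=(4, 4)), rng.normal(size=4))

    def test_nested_models_never_lose_train_r2(self, rng):
        X = rng.normal(size=(40, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=40)
        r2 = []
        for p in range(1, 9):
            m = mlr_fit(X[:, :p], y)
            r2.append(score(y, m.predict(X[:, :p])).r2)
        assert all(0 <= v <= 1 for v in r2)
        assert np.all(np.diff(r2) >= -1e-12)


class TestPLSR:
    def test_full_components_reach_ols(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(size=25)
        pls = plsr_fit(X, y, n_components=6)
        ols = mlr_fit(X, y)
        np.testing.assert_allclose(pls.predict(X), ols.predict(X), atol=1e-8)

    def test_single_column_collapses_to_simple_regression(self, rng):
        x = rng.normal(size=(20, 1))
        y = 1.5 * x[:, 0] + 0.3 + 0.1 * rng.normal(size=20)
        pls = plsr_fit(x, y, n_components=1)
        ols = mlr_fit(x, y)
        np.testing.assert_allclose(pls.predict(x), ols.predict(x), atol=1e-8)

    def test_scores_are_orthogonal(self, rng):
        M = rng.normal(size=(30, 8))
        Q, _ = np.linalg.qr(M)
        X = Q[:, :6]
        y = X @ rng.normal(size=6) + 0.05 * rng.normal(size=30)
        pls = plsr_fit(X, y, n_components=4)
        T = pls.x_scores_
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        np.testing.assert_allclose(off, 0.0, atol=1e-8)

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            plsr_fit(rng.normal(size=(10, 3)), np.ones(10), 2)

    def test_component_bounds(self, rng):
        with pytest.raises(ValueError, match="n_components"):
            plsr_fit(rng.normal(size=(10, 3)), rng.normal(size=10), 5)


class TestPredict:
    def test_column_mismatch(self, rng):
        model = mlr_fit(rng.normal(size=(10, 2)), rng.normal(size=10))
        with pytest.raises(ValueError, match="columns"):
            predict(model, rng.normal(size=(5, 3)))

    def test_duplicate_row_identical_prediction(self, rng):
        X = rng.normal(size=(12, 3))
        model = mlr_fit(X, rng.normal(size=12))
        both = predict(model, np.vstack([X[4], X[4]]))
        assert both[0] == both[1]


class TestScore:
    def test_perfect_fit(self):
        s = score([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s.r2 == 1.0 and s.rmse == 0.0

    def test_mean_predictor_r2_zero(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        s = score(y, np.full(4, y.mean()))
        np.testing.assert_allclose(s.r2, 0.0, atol=1e-15)

    def test_hand_rmse(self):
        s = score([0.0, 0.0], [3.0, 4.0])
        np.testing.assert_allclose(s.rmse, np.sqrt(12.5))

    def test_zero_variance_observations(self):
        s = score([2.0, 2.0], [2.5, 1.5])
        assert s.r2 is None
        np.testing.assert_allclose(s.rmse, 0.5)

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_permutation_invariant(self, perm):
        y = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        y_hat = np.array([2.5, 1.2, 4.4, 1.0, 8.5, 3.0])
        p = np.asarray(perm)
        a, b = score(y, y_hat), score(y[p], y_hat[p])
        np.testing.assert_allclose(a.r2, b.r2)
        np.testing.assert_allclose(a.rmse, b.rmse)

    def test_length_guard(self):
        with pytest.raises(ValueError):
            score([1.0], [1.0])


class TestSerialization:
    def test_json_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(15, 3))
        y = rng.normal(size=15)
        model = mlr_fit(X, y, band_indices=[550, 680, 720])
        out = serialize_model(model, tmp_path / "model.json")
        assert out["kind"] == "MLR"
        assert out["band_indices"] == [550, 680, 720]
        np.testing.assert_allclose(out["coefficients"], model.coef_)
        import json

        with open(tmp_path / "model.json") as fh:
            assert json.load(fh) == out

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = PLSCalibration(n_components=3)
        assert clone(est).n_components == 3
        est2 = MLRCalibration(band_indices=[1, 2])
        assert clone(est2).band_indices == [1, 2]
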