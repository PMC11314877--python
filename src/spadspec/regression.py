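"""MLR and PLSR calibration of SPAD on selected bands, plus metrics.

Both calibrations are ordinary chemometric workhorses: multiple linear
regression (ordinary least squares with intercept) and partial least
squares regression (NIPALS latent components maximizing the covariance
between predictor scores and SPAD, mean-centered, no variance scaling).
Model quality is summarized by the coefficient of determination
R² = 1 − SSres/SStot and RMSE = sqrt(mean squared error) with
denominator n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import qr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelScore",
    "MLRCalibration",
    "PLSCalibration",
    "mlr_fit",
    "plsr_fit",
    "predict",
    "score",
    "serialize_model",
]


@dataclass
class ModelScore:
    """R²/RMSE summary of one prediction set."""

    r2: float | None
    rmse: float
    n: int
    subset: str | None = None


def score(y, y_hat, subset: str | None = None) -> ModelScore:
    """R² and RMSE of predictions against observations.

    R² = 1 − Σ(ŷ−y)²/Σ(y−ȳ)²; RMSE = sqrt(Σ(ŷ−y)²/n).  With
    zero-variance observations R² is undefined and reported as None.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 samples to score")
    ss_res = float(np.sum((y_hat - y) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ModelScore(r2, float(np.sqrt(ss_res / n)), n, subset)


def _collinear_columns(X: np.ndarray, band_indices=None) -> list:
    """Name the columns a pivoted QR flags as (near-)dependent."""
    _, R, piv = qr(X - X.mean(axis=0), mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    thresh = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = piv[np.flatnonzero(diag <= thresh)]
    if band_indices is not None:
        return [band_indices[int(j)] for j in bad]
    return [int(j) for j in bad]


class MLRCalibration(RegressorMixin, BaseEstimator):
    """Multiple linear regression (OLS with intercept) on selected bands.

    Fitting is delegated to a numerically stable least-squares solve;
    rank deficiency raises an error naming the collinear bands.

    Attributes
    ----------
    coef_ : ndarray, SPAD per predictor unit.
    intercept_ : float, SPAD units.
    band_indices_ : channels the columns of X correspond to.
    """

    kind = "MLR"

    def __init__(self, band_indices=None):
        self.band_indices = band_indices

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n <= p + 1:
            raise ValueError(
                f"MLR needs more samples ({n}) than bands + 1 ({p + 1})"
            )
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
            bad = _collinear_columns(X, self.band_indices)
            raise ValueError(f"design matrix is rank deficient; collinear bands: {bad}")
        self._lm = LinearRegression().fit(X, y)
        self.coef_ = self._lm.coef_
        self.intercept_ = float(self._lm.intercept_)
        self.n_features_in_ = p
        self.band_indices_ = (
            list(self.band_indices) if self.band_indices is not None else list(range(p))
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was fit on {self.n_features_in_}"
            )
        return self._lm.predict(X)


class PLSCalibration(RegressorMixin, BaseEstimator):
    """Partial least squares regression (NIPALS, mean-centered, unscaled).

    Parameters
    ----------
    n_components : int, default 2
        Number of latent components (1 <= n_components <= rank of X).
    """

    kind = "PLSR"

    def __init__(self, n_components: int = 2, band_indices=None):
        self.n_components = n_components
        self.band_indices = band_indices

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("y has zero variance; PLSR components are undefined")
        if not 1 <= self.n_components <= min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(
                f"n_components={self.n_components} outside "
                f"[1, {min(X.shape[0] - 1, X.shape[1])}]"
            )
        self._pls = PLSRegression(n_components=self.n_components, scale=False)
        self._pls.fit(X, y)
        self.coef_ = self._pls.coef_.ravel()
        self.intercept_ = float(np.ravel(self._pls.intercept_)[0])
        self.x_scores_ = self._pls.x_scores_
        self.n_features_in_ = X.shape[1]
        self.band_indices_ = (
            list(self.band_indices)
            if self.band_indices is not None
            else list(range(X.shape[1]))
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} columns, model was fit on {self.n_features_in_}"
            )
        return self._pls.predict(X).ravel()


def mlr_fit(X, y, band_indices=None) -> MLRCalibration:
    """Fit ordinary least squares with intercept on the given bands."""
    return MLRCalibration(band_indices=band_indices).fit(X, y)


def plsr_fit(X, y, n_components: int, band_indices=None) -> PLSCalibration:
    """Fit PLSR with the given number of latent components."""
    return PLSCalibration(n_components=n_components, band_indices=band_indices).fit(X, y)


def predict(model, X) -> np.ndarray:
    """Predict SPAD from a fitted calibration model."""
    return model.predict(X)


def serialize_model(model, path=None) -> dict:
    """JSON-serializable description of a fitted calibration model."""
    check_is_fitted(model, "coef_")
    out = {
        "kind": model.kind,
        "band_indices": [int(i) for i in model.band_indices_],
        "coefficients": [float(c) for c in np.ravel(model.coef_)],
        "intercept": float(model.intercept_),
        "n_components": int(getattr(model, "n_components", 0)) or None,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(out, fh, indent=2)
    return out
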