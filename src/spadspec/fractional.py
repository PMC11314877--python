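"""Grünwald–Letnikov fractional-order differentiation of spectra.

The G-L derivative of order ``alpha`` generalizes discrete differencing:
at channel i the derivative is

    D^a r(i) = (1 / h^a) * sum_{k=0..i} w_k * r(i - k),

with binomial-type weights w_k = (-1)^k C(alpha, k), computed by the
stable recurrence w_0 = 1, w_k = w_{k-1} * (k - 1 - alpha) / k.  For
alpha = 0 this is the identity; for alpha = 1 and 2 it reduces to the
backward first and second differences.  The window expands from the
first retained channel (the full left history), so the first few
channels of each transform are edge-affected; their count is carried on
the sweep so downstream band selection can mask them if desired.

Non-integer orders between 0 and 2 interpolate between the raw curve
and its first/second derivatives, which is what makes the 21-order
sweep (0 to 2, step 0.1) a useful family of candidate preprocessings
for chlorophyll calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import toeplitz
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectraSet, Spectrum

__all__ = [
    "GLWeights",
    "DerivativeSweep",
    "gl_coefficients",
    "fractional_derivative",
    "fractional_derivative_matrix",
    "derivative_sweep",
    "GLFractionalDifferentiator",
]

#: Channels counted as edge-affected by the expanding-history window.
EDGE_WIDTH = 20


@dataclass
class GLWeights:
    """Truncated G-L coefficient sequence for one order."""

    alpha: float
    weights: np.ndarray
    m: int


def gl_coefficients(alpha: float, m: int) -> GLWeights:
    """G-L weights w_0..w_m for order ``alpha``.

    Uses the recurrence w_k = w_{k-1} (k - 1 - alpha) / k, equivalent to
    (-1)^k * Gamma(alpha+1) / (k! * Gamma(alpha-k+1)) but free of Gamma
    poles at integer orders.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if m < 0:
        raise ValueError("m must be >= 0")
    k = np.arange(1, m + 1, dtype=float)
    w = np.empty(m + 1)
    w[0] = 1.0
    if m:
        w[1:] = np.cumprod((k - 1.0 - alpha) / k)
    return GLWeights(float(alpha), w, m)


def fractional_derivative_matrix(
    X: np.ndarray, alpha: float, step_h: float = 1.0
) -> np.ndarray:
    """Apply the G-L derivative of order ``alpha`` row-wise to a matrix.

    Channel i of each row becomes sum_k w_k x[i-k] / step_h**alpha, the
    expanding left-history window starting at the first column.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if alpha == 0:
        return X / step_h**0  # identity, exactly
    w = gl_coefficients(alpha, p - 1).weights
    # lower-triangular Toeplitz operator T[i, j] = w[i - j]
    T = toeplitz(w, np.zeros(p))
    return (X @ T.T) / step_h**alpha


def fractional_derivative(
    spectrum: Spectrum, alpha: float, step_h: float | None = None
) -> Spectrum:
    """G-L fractional derivative of one spectrum on a uniform grid."""
    dw = np.diff(spectrum.wavelengths)
    if dw.size and not np.allclose(dw, dw[0], rtol=1e-6, atol=1e-9):
        raise ValueError(
            "wavelength grid is not uniform; resample to a uniform grid "
            "(resample_to_grid) before fractional differentiation"
        )
    h = float(dw[0]) if step_h is None else float(step_h)
    if step_h is not None and dw.size and not np.isclose(h, dw[0], rtol=1e-6):
        raise ValueError(f"step_h={h} does not match the grid spacing {dw[0]}")
    out = spectrum.copy()
    out.reflectance = fractional_derivative_matrix(
        spectrum.reflectance[None, :], alpha, h
    )[0]
    return out


class GLFractionalDifferentiator(TransformerMixin, BaseEstimator):
    """Stateless transformer applying one G-L fractional derivative.

    Parameters
    ----------
    alpha : float, default 1.0
        Differentiation order (>= 0).
    step_h : float, default 1.0
        Uniform grid spacing in nm; the derivative is scaled by
        ``step_h ** -alpha``.
    """

    def __init__(self, alpha: float = 1.0, step_h: float = 1.0):
        self.alpha = alpha
        self.step_h = step_h

    def fit(self, X, y=None):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.step_h <= 0:
            raise ValueError("step_h must be > 0")
        self.n_features_in_ = np.atleast_2d(np.asarray(X)).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        return fractional_derivative_matrix(X, self.alpha, self.step_h)


def _order_grid(lo: float, hi: float, step: float) -> list[float]:
    if step <= 0:
        raise ValueError("step must be > 0")
    if lo > hi:
        raise ValueError("lo must be <= hi")
    orders = []
    k = 0
    while lo + k * step <= hi + 1e-9:
        orders.append(round(lo + k * step, 10))
        k += 1
    return orders


@dataclass
class DerivativeSweep:
    """All fractional-order transforms of one spectra matrix."""

    orders: list[float]
    transforms: dict[float, np.ndarray]
    grid: np.ndarray
    step_h: float
    edge_width: int = EDGE_WIDTH
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.transforms) != len(self.orders):
            raise ValueError("one transform per order required")
        if not self.labels:
            self.labels = [f"{a:.1f}" for a in self.orders]

    def write(self, out_dir) -> None:
        """Persist one CSV per order plus a JSON manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        for a, label in zip(self.orders, self.labels):
            pd.DataFrame(
                self.transforms[a], columns=[str(w) for w in self.grid]
            ).to_csv(out_dir / f"derivative_order_{label}.csv", index=False)
        with open(out_dir / "sweep_manifest.json", "w") as fh:
            json.dump(
                {
                    "orders": self.orders,
                    "labels": self.labels,
                    "step_h": self.step_h,
                    "edge_width": self.edge_width,
                },
                fh,
                indent=2,
            )


def derivative_sweep(
    sset: SpectraSet | np.ndarray,
    lo: float = 0.0,
    hi: float = 2.0,
    step: float = 0.1,
    step_h: float | None = None,
) -> DerivativeSweep:
    """Transform a spectra matrix at every order lo, lo+step, ..., hi.

    The default grid 0 -> 2 in steps of 0.1 yields 21 transforms.
    """
    if isinstance(sset, SpectraSet):
        X = sset.reflectance
        grid = sset.wavelengths
        dw = np.diff(grid)
        if dw.size and not np.allclose(dw, dw[0], rtol=1e-6, atol=1e-9):
            raise ValueError(
                "wavelength grid is not uniform; resample before the sweep"
            )
        h = float(dw[0]) if step_h is None and dw.size else float(step_h or 1.0)
    else:
        X = np.atleast_2d(np.asarray(sset, dtype=float))
        grid = np.arange(X.shape[1], dtype=float)
        h = float(step_h or 1.0)
    orders = _order_grid(lo, hi, step)
    transforms = {
        a: fractional_derivative_matrix(X, a, h) for a in orders
    }
    return DerivativeSweep(orders, transforms, np.asarray(grid, dtype=float), h)
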