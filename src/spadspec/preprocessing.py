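"""Quality control, five-point weighted smoothing, resampling, cropping.

Field spectra carry "burr" spike noise and occasional pathological
samples (missing bands, abnormal jumps).  The cleaning stage here is:
reject bad samples, smooth each curve with a five-point weighted moving
average, put everything on a uniform 1 nm grid, and crop to the
modelling range.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import SpectraSet, Spectrum

__all__ = [
    "QCReport",
    "FivePointSmoother",
    "quality_filter",
    "smooth_five_point",
    "resample_to_grid",
    "crop_range",
]

#: Symmetric centre-weighted default kernel; the field-standard choice
#: for five-point weighted moving-average smoothing.
DEFAULT_WEIGHTS = (1.0, 2.0, 4.0, 2.0, 1.0)

#: Physically plausible reflectance bounds used by quality control.
QC_BOUNDS = (-0.05, 1.5)


@dataclass
class QCReport:
    """Outcome of :func:`quality_filter`."""

    n_input: int
    n_removed: int
    removal_reasons: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_input": self.n_input,
                    "n_removed": self.n_removed,
                    "removal_reasons": self.removal_reasons,
                },
                fh,
                indent=2,
            )


def quality_filter(
    sset: SpectraSet,
    max_abs_jump: float = 0.3,
    allow_missing: bool = False,
    bounds: tuple[float, float] = QC_BOUNDS,
) -> tuple[SpectraSet, QCReport]:
    """Drop samples with missing channels, out-of-range reflectance, or jumps.

    A sample is removed if it contains NaN (unless ``allow_missing``),
    any reflectance outside ``bounds``, or an adjacent-channel absolute
    difference exceeding ``max_abs_jump``.  The report records one reason
    per removed sample (checked in that order).
    """
    if max_abs_jump <= 0:
        raise ValueError("max_abs_jump must be > 0")
    reasons: dict[str, str] = {}
    keep = []
    for i in range(len(sset)):
        r = sset.reflectance[i]
        sid = sset.sample_ids[i]
        if not allow_missing and np.any(np.isnan(r)):
            reasons[sid] = "missing"
        elif np.any((r < bounds[0]) | (r > bounds[1])):
            reasons[sid] = "range"
        elif np.any(np.abs(np.diff(r)) > max_abs_jump):
            reasons[sid] = "jump"
        else:
            keep.append(i)
    if not keep:
        raise ValueError(
            "quality_filter removed every sample; review max_abs_jump/bounds"
        )
    report = QCReport(len(sset), len(sset) - len(keep), reasons)
    return sset.subset(np.asarray(keep)), report


def _validate_weights(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if w.shape != (5,):
        raise ValueError("weights must be a length-5 vector")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    return w


def _smooth_matrix(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    # Truncated, renormalized window at the edges: divide the raw
    # correlation by the correlation of an all-ones signal.  An edge
    # channel whose truncated window carries zero total weight (possible
    # with one-sided kernels) is left unsmoothed.
    num = correlate1d(X, w, axis=-1, mode="constant", cval=0.0)
    den = correlate1d(np.ones_like(X), w, axis=-1, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), X)
    return out


class FivePointSmoother(TransformerMixin, BaseEstimator):
    """Five-point weighted moving-average smoother.

    Channel i of the output is the weighted average of channels
    i-2..i+2; the first and last two channels use the truncated,
    renormalized window.  Stateless: ``fit`` only validates the kernel.

    Parameters
    ----------
    weights : sequence of 5 non-negative floats, default (1, 2, 4, 2, 1)
        Smoothing kernel; it is normalized internally.
    """

    def __init__(self, weights=DEFAULT_WEIGHTS):
        self.weights = weights

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[-1] < 5:
            raise ValueError("spectra must have at least 5 channels")
        self.weights_ = _validate_weights(self.weights)
        self.n_features_in_ = X.shape[-1]
        return self

    def transform(self, X):
        check_is_fitted(self, "weights_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[-1] < 5:
            raise ValueError("spectra must have at least 5 channels")
        return _smooth_matrix(X, self.weights_)


def smooth_five_point(
    spectrum: Spectrum, weights=DEFAULT_WEIGHTS
) -> Spectrum:
    """Smooth one spectrum with the five-point weighted moving average."""
    if spectrum.n_channels < 5:
        raise ValueError("spectrum must have at least 5 channels")
    out = spectrum.copy()
    out.reflectance = _smooth_matrix(
        spectrum.reflectance[None, :], _validate_weights(weights)
    )[0]
    return out


def smooth_set(sset: SpectraSet, weights=DEFAULT_WEIGHTS) -> SpectraSet:
    """Smooth every sample of a :class:`SpectraSet`."""
    out = sset.subset(np.arange(len(sset)))
    out.reflectance = _smooth_matrix(out.reflectance, _validate_weights(weights))
    return out


def resample_to_grid(spectrum: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    lo, hi = spectrum.wavelengths[0], spectrum.wavelengths[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond the spectrum span "
            f"[{lo}, {hi}]; extrapolation is not supported"
        )
    return Spectrum(
        grid,
        np.interp(grid, spectrum.wavelengths, spectrum.reflectance),
        spectrum.sample_id,
        spectrum.group,
        spectrum.spad,
    )


def crop_range(sset: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Keep channels with lo <= wavelength <= hi; metadata unchanged."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    mask = (sset.wavelengths >= lo) & (sset.wavelengths <= hi)
    if not np.any(mask):
        raise ValueError(
            f"crop range [{lo}, {hi}] does not overlap the grid "
            f"[{sset.wavelengths[0]}, {sset.wavelengths[-1]}]"
        )
    return SpectraSet(
        sset.wavelengths[mask],
        sset.reflectance[:, mask],
        list(sset.sample_ids),
        list(sset.groups),
        None if sset.spad is None else sset.spad.copy(),
    )
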