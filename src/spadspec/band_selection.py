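"""Successive projections algorithm (SPA) wavelength selection.

SPA grows a chain of channels: starting from a seed column, each step
projects every unselected column onto the orthogonal complement of the
span of the already-selected columns and appends the column with the
largest projected norm.  The chain therefore accumulates channels with
minimal mutual collinearity.  Candidate chains are grown from every
start channel (and, optionally, every length in a range); the chain
whose channels give the lowest multiple-linear-regression RMSE on a
validation set wins.

All candidate chains are grown simultaneously with a batched
Gram–Schmidt update, and all candidate subsets are scored with batched
least squares, so the full start scan stays fast even on ~10^3-channel
spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .fractional import DerivativeSweep

__all__ = ["BandSelection", "spa_chain", "spa_select", "selection_map", "SPABandSelector"]

_TOL = 1e-12


@dataclass
class BandSelection:
    """Result of one SPA selection run."""

    selected_indices: np.ndarray  # chain order
    selected_wavelengths: np.ndarray | None
    n_selected: int
    start_index: int
    validation_rmse: float
    order_alpha: float | None = None

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if self.selected_wavelengths is not None:
            self.selected_wavelengths = np.asarray(self.selected_wavelengths, float)
        if len(set(self.selected_indices.tolist())) != self.selected_indices.size:
            raise ValueError("selected indices must be unique")
        if self.n_selected != self.selected_indices.size:
            raise ValueError("n_selected must equal len(selected_indices)")
        if self.validation_rmse < 0:
            raise ValueError("validation_rmse must be >= 0")


def spa_chain(X: np.ndarray, start: int, n_max: int) -> np.ndarray:
    """Grow one SPA chain of length ``n_max`` from column ``start``.

    Ties in the projected norm break toward the lowest channel index.
    If every remaining projected norm falls below 1e-12 the chain is
    truncated with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if not 0 <= start < p:
        raise IndexError(f"start column {start} out of range [0, {p})")
    if n_max < 1 or n_max > p:
        raise ValueError("n_max must be in [1, n_channels]")
    R = X.copy()
    chain = [start]
    for _ in range(n_max - 1):
        q = R[:, chain[-1]]
        nq = np.linalg.norm(q)
        if nq < _TOL:
            warnings.warn("SPA chain truncated: selected column has ~zero residual")
            break
        q = q / nq
        R -= np.outer(q, q @ R)
        norms = np.linalg.norm(R, axis=0)
        norms[chain] = -np.inf
        j = int(np.argmax(norms))  # first max -> lowest index on ties
        if norms[j] < _TOL:
            warnings.warn(
                "SPA chain truncated: all remaining projected norms below 1e-12"
            )
            break
        chain.append(j)
    return np.asarray(chain, dtype=int)


def _batched_chains(
    X: np.ndarray, starts: np.ndarray, n_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Grow SPA chains from every start at once.

    Uses the Gram-matrix (incremental Cholesky) formulation: the squared
    residual norm of every column after projecting out the selected span
    is tracked by rank-one downdates of diag(X'X), which is equivalent
    to explicit Gram-Schmidt deflation but touches O(p) memory per start
    and step instead of O(n*p).

    Returns (chains, lengths): chains is (n_starts, n_max) with unused
    tail entries = -1; lengths gives each chain's usable length.
    """
    n, p = X.shape
    S = starts.size
    G = X.T @ X  # (p, p) Gram matrix
    chains = np.full((S, n_max), -1, dtype=int)
    chains[:, 0] = starts
    lengths = np.ones(S, dtype=int)
    alive = np.ones(S, dtype=bool)
    # A[s, t, :] holds <q_t, x_j> for chain s (rows of the Cholesky factor)
    A = np.zeros((S, n_max, p))
    d0 = np.diag(G).copy()
    d = np.broadcast_to(d0, (S, p)).copy()  # residual sq norms
    # the rank-one downdates cancel to O(eps * d0), so degeneracy is
    # detected relative to each column's original squared norm
    dead_sq = np.maximum(_TOL**2, 1e-12 * d0)
    rows = np.arange(S)
    for t in range(n_max):
        cur = chains[:, t]
        cur_safe = np.where(cur < 0, 0, cur)
        nsq = d[rows, cur_safe]
        dead = alive & (nsq < dead_sq[cur_safe])
        alive &= ~dead
        lengths[dead] = np.maximum(t, 1)  # keep the seed even if degenerate
        if not alive.any():
            break
        g = G[cur_safe]  # (S, p)
        if t:
            coef = np.take_along_axis(
                A[:, :t, :], cur_safe[:, None, None], axis=2
            )[:, :, 0]  # (S, t)
            g = g - np.einsum("st,stp->sp", coef, A[:, :t, :])
        a = g / np.sqrt(np.maximum(nsq, _TOL**2))[:, None]
        A[:, t, :] = np.where(alive[:, None], a, 0.0)
        d = np.maximum(d - A[:, t, :] ** 2, 0.0)
        if t + 1 == n_max:
            break
        dn = np.where(d < dead_sq, -np.inf, d)
        np.put_along_axis(dn, chains[:, : t + 1].clip(min=0), -np.inf, axis=1)
        nxt = np.argmax(dn, axis=1)  # first max -> lowest index on ties
        best = np.take_along_axis(dn, nxt[:, None], axis=1)[:, 0]
        ok = alive & np.isfinite(best)
        chains[ok, t + 1] = nxt[ok]
        lengths[ok] = t + 2
        alive = ok
    return chains, lengths


def _batched_val_rmse(
    Xc_tr: np.ndarray,
    y_tr: np.ndarray,
    Xc_val: np.ndarray,
    y_val: np.ndarray,
    chains: np.ndarray,
    n: int,
) -> np.ndarray:
    """Validation RMSE of MLR fits on the first ``n`` bands of every chain."""
    S = chains.shape[0]
    idx = chains[:, :n]
    A = np.transpose(Xc_tr[:, idx], (1, 0, 2))  # (S, n_tr, n)
    A1 = np.concatenate([np.ones((S, A.shape[1], 1)), A], axis=2)
    beta = np.linalg.pinv(A1) @ y_tr  # (S, n+1)
    V = np.transpose(Xc_val[:, idx], (1, 0, 2))
    V1 = np.concatenate([np.ones((S, V.shape[1], 1)), V], axis=2)
    pred = np.einsum("svk,sk->sv", V1, beta)
    return np.sqrt(np.mean((pred - y_val[None, :]) ** 2, axis=1))


def spa_select(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    n_min: int = 1,
    n_max: int = 10,
    fixed_n: int | None = None,
    starts: np.ndarray | None = None,
    wavelengths: np.ndarray | None = None,
) -> BandSelection:
    """SPA selection over every start channel and chain length.

    Columns are mean-centered with the training means before the
    projections and fits.  For each candidate (start, length) the chain's
    bands feed an intercepted least-squares fit on the training rows,
    scored by RMSE on the validation rows; the minimizer wins, ties going
    to the smaller length and then the lower start index.

    ``fixed_n`` restricts the scan to one chain length (the pipeline
    default keeps 10 bands).
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    X_val = np.atleast_2d(np.asarray(X_val, dtype=float))
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    n_tr, p = X_train.shape
    if X_val.shape[1] != p:
        raise ValueError("train and validation channel counts differ")
    if fixed_n is not None:
        n_min = n_max = int(fixed_n)
    if n_min < 1:
        raise ValueError("n_min must be >= 1")
    if n_max > p:
        raise ValueError("n_max exceeds the channel count")
    if n_max >= n_tr:
        raise ValueError(
            f"n_max={n_max} bands with only {n_tr} training samples is rank "
            "deficient; reduce n_max or add samples"
        )
    mu = X_train.mean(axis=0)
    Xc_tr = X_train - mu
    Xc_val = X_val - mu
    if starts is None:
        starts = np.arange(p)
    else:
        starts = np.asarray(starts, dtype=int)

    chains, lengths = _batched_chains(Xc_tr, starts, n_max)
    cap = int(lengths.max())
    if cap < n_min:
        warnings.warn(
            f"SPA chains truncated at {cap} band(s); evaluating at that length"
        )
        sizes = [cap]
    else:
        sizes = [n for n in range(max(n_min, 1), min(n_max, cap) + 1)]

    best = (np.inf, -1, -1)  # rmse, n, start row
    for n in sizes:  # ascending: ties keep the smaller subset
        rmse = _batched_val_rmse(Xc_tr, y_train, Xc_val, y_val, chains, n)
        rmse[lengths < n] = np.inf
        s = int(np.argmin(rmse))  # first min -> lowest start on ties
        if rmse[s] < best[0]:
            best = (float(rmse[s]), n, s)
    if best[1] < 0:
        raise ValueError("SPA selection failed: no evaluable chain")
    rmse, n_sel, srow = best
    idx = chains[srow, :n_sel]
    return BandSelection(
        selected_indices=idx,
        selected_wavelengths=None if wavelengths is None else np.asarray(wavelengths)[idx],
        n_selected=n_sel,
        start_index=int(starts[srow]),
        validation_rmse=rmse,
    )


def selection_map(
    sweep: DerivativeSweep,
    spad: np.ndarray,
    train_mask: np.ndarray,
    n_bands: int = 10,
    mask_edges: bool = False,
) -> dict[float, BandSelection]:
    """Run SPA selection independently on every order of a sweep.

    ``train_mask`` (boolean, fixed across orders) splits the rows into
    training and validation.  With ``mask_edges`` the first
    ``sweep.edge_width`` channels are excluded from the chain seeds.
    """
    spad = np.asarray(spad, dtype=float)
    train_mask = np.asarray(train_mask, dtype=bool)
    starts = None
    if mask_edges:
        starts = np.arange(sweep.edge_width, sweep.grid.size)
    out: dict[float, BandSelection] = {}
    for a in sweep.orders:
        X = sweep.transforms[a]
        sel = spa_select(
            X[train_mask],
            spad[train_mask],
            X[~train_mask],
            spad[~train_mask],
            fixed_n=n_bands,
            starts=starts,
            wavelengths=sweep.grid,
        )
        sel.order_alpha = a
        out[a] = sel
    return out


def selection_table(selections: dict[float, BandSelection]) -> pd.DataFrame:
    """Flatten a per-order selection map into a tidy table."""
    rows = []
    for a, sel in selections.items():
        for rank, (idx, wl) in enumerate(
            zip(
                sel.selected_indices,
                sel.selected_wavelengths
                if sel.selected_wavelengths is not None
                else sel.selected_indices,
            ),
            start=1,
        ):
            rows.append(
                {
                    "order": a,
                    "rank": rank,
                    "wavelength_nm": float(wl),
                    "channel_index": int(idx),
                    "start_index": sel.start_index,
                    "validation_rmse": sel.validation_rmse,
                }
            )
    return pd.DataFrame(rows)


class SPABandSelector(BaseEstimator):
    """Sklearn-style transformer wrapping :func:`spa_select`.

    Parameters
    ----------
    n_bands : int or None, default 10
        Fixed chain length.  If None, every length in
        ``[n_min, n_max]`` competes on validation RMSE.
    n_min, n_max : int
        Length range scanned when ``n_bands`` is None.
    validation_fraction : float, default 1/3
        Fraction of the fit rows held out for chain scoring when no
        explicit validation set is passed to :meth:`fit`.
    random_state : int, default 0
        Seed of the internal holdout split.

    Attributes
    ----------
    selected_indices_ : ndarray of int
        Chosen channels in chain order.
    support_ : boolean mask over channels.
    validation_rmse_ : float
    start_index_ : int
    """

    def __init__(
        self,
        n_bands: int | None = 10,
        n_min: int = 1,
        n_max: int = 10,
        validation_fraction: float = 1 / 3,
        random_state: int = 0,
    ):
        self.n_bands = n_bands
        self.n_min = n_min
        self.n_max = n_max
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if X_val is None:
            rng = np.random.default_rng(self.random_state)
            perm = rng.permutation(len(y))
            n_hold = max(1, int(round(self.validation_fraction * len(y))))
            hold, keep = perm[:n_hold], perm[n_hold:]
            X, X_val = X[keep], X[hold]
            y, y_val = y[keep], y[hold]
        sel = spa_select(
            X,
            y,
            X_val,
            np.asarray(y_val, dtype=float),
            n_min=self.n_min,
            n_max=self.n_max,
            fixed_n=self.n_bands,
        )
        self.n_features_in_ = X.shape[1]
        self.selected_indices_ = sel.selected_indices
        self.support_ = np.zeros(self.n_features_in_, dtype=bool)
        self.support_[sel.selected_indices] = True
        self.validation_rmse_ = sel.validation_rmse
        self.start_index_ = sel.start_index
        return self

    def transform(self, X):
        check_is_fitted(self, "selected_indices_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("channel count differs from fit")
        return X[:, self.selected_indices_]

    def get_support(self, indices: bool = False):
        check_is_fitted(self, "support_")
        return self.selected_indices_.copy() if indices else self.support_.copy()
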