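"""SPA chain growth and validation-scored band selection."""

import warnings

import numpy as np
import pytest

from spadspec import SPABandSelector, selection_map, spa_chain, spa_select
from spadspec.fractional import derivative_sweep


def oracle_chain(X, start, n_max):
    """Brute-force SPA: re-orthogonalize every candidate from scratch
    against the selected columns via least squares at every step."""
    chain = [start]
    for _ in range(n_max - 1):
        S = X[:, chain]
        best, best_norm = None, -np.inf
        for j in range(X.shape[1]):
            if j in chain:
                continue
            beta, *_ = np.linalg.lstsq(S, X[:, j], rcond=None)
            res = X[:, j] - S @ beta
            norm = np.linalg.norm(res)
            if norm > best_norm + 1e-12:
                best, best_norm = j, norm
        if best_norm < 1e-12:
            break
        chain.append(best)
    return np.asarray(chain)


class TestSpaChain:
    def test_orthogonal_columns_ordered_by_norm(self):
        """With orthogonal columns projections change nothing, so the
        chain walks the remaining columns in descending norm."""
        X = np.diag([3.0, 5.0, 1.0, 4.0])
        chain = spa_chain(X, start=1, n_max=4)
        np.testing.assert_array_equal(chain, [1, 3, 0, 2])

    def test_hand_gram_schmidt_example(self):
        """c3=(1,1) start; residuals of c1, c2 tie at sqrt(0.5); the
        lower index wins."""
        X = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0]])
        chain = spa_chain(X, start=2, n_max=2)
        np.testing.assert_array_equal(chain, [2, 0])

    def test_matches_exhaustive_oracle(self):
        for seed in range(100):
            X = np.random.default_rng(seed).normal(size=(8, 5))
            X -= X.mean(axis=0)
            start = seed % 5
            np.testing.assert_array_equal(
                spa_chain(X, start, 4), oracle_chain(X, start, 4)
            )

    def test_start_out_of_range(self):
        with pytest.raises(IndexError):
            spa_chain(np.ones((3, 2)), start=5, n_max=1)

    def test_duplicate_columns_truncate_with_warning(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 4))
        with pytest.warns(UserWarning, match="truncated"):
            chain = spa_chain(X - X.mean(0), start=1, n_max=3)
        assert chain.size == 1


class TestSpaSelect:
    def test_single_informative_column_found(self, rng):
        X_tr = rng.normal(size=(30, 12))
        X_val = rng.normal(size=(15, 12))
        j = 7
        sel = spa_select(X_tr, 3.0 * X_tr[:, j], X_val, 3.0 * X_val[:, j], fixed_n=1)
        np.testing.assert_array_equal(sel.selected_indices, [j])
        assert sel.validation_rmse < 1e-8

    def test_fixed_n_ten_selects_ten(self, rng):
        X_tr = rng.normal(size=(40, 30))
        X_val = rng.normal(size=(20, 30))
        y_tr, y_val = rng.normal(size=40), rng.normal(size=20)
        sel = spa_select(X_tr, y_tr, X_val, y_val, fixed_n=10)
        assert sel.n_selected == 10
        assert len(set(sel.selected_indices.tolist())) == 10

    def test_identical_columns_truncate_with_warning(self, rng):
        col_tr, col_val = rng.normal(size=30), rng.normal(size=15)
        X_tr = np.tile(col_tr[:, None], (1, 6))
        X_val = np.tile(col_val[:, None], (1, 6))
        with pytest.warns(UserWarning, match="truncated"):
            sel = spa_select(X_tr, col_tr, X_val, col_val, fixed_n=3)
        assert sel.n_selected == 1

    def test_rank_deficiency_guard(self, rng):
        X = rng.normal(size=(8, 20))
        with pytest.raises(ValueError, match="rank"):
            spa_select(X, rng.normal(size=8), X, rng.normal(size=8), fixed_n=10)

    def test_reproducible(self, rng):
        X_tr = rng.normal(size=(25, 40))
        X_val = rng.normal(size=(12, 40))
        y_tr, y_val = rng.normal(size=25), rng.normal(size=12)
        a = spa_select(X_tr, y_tr, X_val, y_val, fixed_n=5)
        b = spa_select(X_tr, y_tr, X_val, y_val, fixed_n=5)
        np.testing.assert_array_equal(a.selected_indices, b.selected_indices)
        assert a.validation_rmse == b.validation_rmse

    def test_scanned_length_never_beats_fixed(self, rng):
        """Scanning n in [1, 5] can only improve the validation RMSE."""
        X_tr = rng.normal(size=(30, 25))
        X_val = rng.normal(size=(15, 25))
        y_tr = X_tr[:, 3] - 2 * X_tr[:, 11] + 0.1 * rng.normal(size=30)
        y_val = X_val[:, 3] - 2 * X_val[:, 11] + 0.1 * rng.normal(size=15)
        fixed = spa_select(X_tr, y_tr, X_val, y_val, fixed_n=5)
        scanned = spa_select(X_tr, y_tr, X_val, y_val, n_min=1, n_max=5)
        assert scanned.validation_rmse <= fixed.validation_rmse + 1e-12

    def test_collinearity_control_vs_random_subsets(self):
        """On noise-free spectra — where channel collinearity is the
        binding constraint — the SPA-selected submatrix is far better
        conditioned than the median random subset of equal size."""
        from spadspec import SyntheticConfig, generate_dataset, split_train_validation

        cfg = SyntheticConfig(step=5.0, n_per_group=12, noise_sd=0.0, seed=7)
        sset = generate_dataset(cfg)
        split = split_train_validation(sset, seed=0)
        tr = split.train_mask(sset.sample_ids)
        X = sset.reflectance
        sel = spa_select(
            X[tr], sset.spad[tr], X[~tr], sset.spad[~tr], fixed_n=6
        )
        Xc = X[tr] - X[tr].mean(0)
        cond_sel = np.linalg.cond(Xc[:, sel.selected_indices])
        rng = np.random.default_rng(0)
        conds = [
            np.linalg.cond(Xc[:, rng.choice(X.shape[1], 6, replace=False)])
            for _ in range(50)
        ]
        assert cond_sel <= np.median(conds)


class TestSelectionMap:
    def test_one_selection_per_order(self, small_dataset):
        sweep = derivative_sweep(small_dataset, 0.0, 2.0, 0.1)
        tr = np.zeros(len(small_dataset), dtype=bool)
        tr[:: 3] = False
        tr[np.arange(len(small_dataset)) % 3 != 0] = True
        sels = selection_map(sweep, small_dataset.spad, tr, n_bands=5)
        assert len(sels) == 21
        assert {s.order_alpha for s in sels.values()} == set(sweep.orders)

    def test_order_zero_equals_direct_selection(self, small_dataset):
        sweep = derivative_sweep(small_dataset, 0.0, 0.5, 0.5)
        tr = np.arange(len(small_dataset)) % 3 != 0
        sels = selection_map(sweep, small_dataset.spad, tr, n_bands=4)
        X = small_dataset.reflectance
        direct = spa_select(
            X[tr],
            small_dataset.spad[tr],
            X[~tr],
            small_dataset.spad[~tr],
            fixed_n=4,
            wavelengths=small_dataset.wavelengths,
        )
        np.testing.assert_array_equal(
            sels[0.0].selected_indices, direct.selected_indices
        )
        assert sels[0.0].validation_rmse == direct.validation_rmse

    def test_signal_region_recovered(self):
        """On noise-free spectra only the visible/red-edge region encodes
        SPAD, so every order's winning selection must reach into it."""
        from spadspec import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(step=5.0, noise_sd=0.0, n_per_group=12, seed=3)
        sset = generate_dataset(cfg)
        tr = np.arange(len(sset)) % 3 != 0
        sweep = derivative_sweep(sset, 0.0, 2.0, 0.5)
        sels = selection_map(sweep, sset.spad, tr, n_bands=3)
        for sel in sels.values():
            assert np.any(sel.selected_wavelengths <= 800), sel.order_alpha


class TestSPABandSelectorEstimator:
    def test_fit_transform_roundtrip(self, rng):
        X = rng.normal(size=(40, 20))
        y = X[:, 2] + 0.5 * X[:, 9] + 0.05 * rng.normal(size=40)
        est = SPABandSelector(n_bands=4, random_state=1).fit(X, y)
        out = est.transform(X)
        assert out.shape == (40, 4)
        assert est.get_support().sum() == 4
        np.testing.assert_array_equal(
            np.sort(est.get_support(indices=True)),
            np.sort(est.selected_indices_),
        )

    def test_explicit_validation_set(self, rng):
        X = rng.normal(size=(30, 15))
        y = X[:, 5]
        est = SPABandSelector(n_bands=1).fit(X, y, X_val=X, y_val=y)
        np.testing.assert_array_equal(est.selected_indices_, [5])

    def test_sklearn_params_round_trip(self):
        est = SPABandSelector(n_bands=7, random_state=3)
        params = est.get_params()
        assert params["n_bands"] == 7
        est.set_params(n_bands=2)
        assert est.n_bands == 2
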