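"""SPA projection chains, exhaustive SPA selection, and CARS."""

import numpy as np
import pytest

from pelletchem.selection import (
    SPASelector,
    cars_select,
    spa_project_chain,
    spa_select,
)

def _orthogonal_columns(norms):
    """Zero-mean, mutually orthogonal columns with the given norms (m=4)."""
    base = np.array(
        [
            [1.0, -1.0, 0.0, 0.0],
            [1.0, 1.0, -2.0, 0.0],
            [1.0, 1.0, 1.0, -3.0],
        ]
    ).T  # Helmert-style: zero-mean and mutually orthogonal
    base = base / np.linalg.norm(base, axis=0)
    return base * np.asarray(norms)


class TestProjectChain:
    def test_orthogonal_columns_ordered_by_norm(self):
        X = _orthogonal_columns([3.0, 2.0, 1.0])
        # orthogonality preserves projected norms, so from the norm-2 start
        # the chain continues with the largest remaining norm
        assert spa_project_chain(X, start_index=1, chain_length=3) == [1, 0, 2]

    def test_exactly_collinear_column_never_selected(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=8)
        a -= a.mean()
        c = rng.normal(size=8)
        c -= c.mean()
        X = np.column_stack([a, 2.0 * a, c])
        with pytest.warns(UserWarning, match="truncated"):
            chain = spa_project_chain(X, start_index=0, chain_length=3)
        assert 1 not in chain  # duplicate of the start column

    def test_stepwise_argmax_matches_orthocomplement_bruteforce(self, rng):
        # independent oracle: residual norm of each candidate after explicit
        # least-squares projection onto the selected columns
        X = rng.normal(size=(10, 6))
        X -= X.mean(axis=0)
        chain = spa_project_chain(X, start_index=2, chain_length=5)
        for step in range(1, len(chain)):
            basis = X[:, chain[:step]]
            resid_norms = []
            for j in range(6):
                coeffs, *_ = np.linalg.lstsq(basis, X[:, j], rcond=None)
                resid_norms.append(np.linalg.norm(X[:, j] - basis @ coeffs))
            candidates = [j for j in range(6) if j not in chain[:step]]
            best = max(candidates, key=lambda j: resid_norms[j])
            assert np.isclose(resid_norms[chain[step]], resid_norms[best])

    def test_no_duplicates(self, rng):
        X = rng.normal(size=(30, 12))
        X -= X.mean(axis=0)
        chain = spa_project_chain(X, 0, 10)
        assert len(chain) == len(set(chain))

    def test_chain_length_bound(self, rng):
        X = rng.normal(size=(5, 10))
        with pytest.raises(ValueError):
            spa_project_chain(X, 0, 7)


class TestSpaSelect:
    def test_single_informative_band_found(self, rng):
        X = rng.normal(size=(40, 12))
        y = X[:, 7].copy()
        Xv = rng.normal(size=(15, 12))
        yv = Xv[:, 7].copy()
        result = spa_select(X, y, Xv, yv, n_min=1, n_max=4)
        assert 7 in result.selected_indices
        assert result.rmsev < 1e-8

    def test_winning_rmse_is_global_minimum(self, rng):
        X = rng.normal(size=(25, 8))
        beta = rng.normal(size=8)
        y = X @ beta + rng.normal(scale=0.5, size=25)
        Xv = rng.normal(size=(10, 8))
        yv = Xv @ beta + rng.normal(scale=0.5, size=10)
        result = spa_select(X, y, Xv, yv, n_min=2, n_max=5)
        assert result.rmsev == min(result.rmsev_by_size.values())
        assert result.chosen_size == min(
            (s for s, r in result.rmsev_by_size.items() if r == result.rmsev)
        )

    @pytest.mark.parametrize(
        "size,expected", [(20, 9.26), (10, 4.63), (17, 7.87)]
    )
    def test_retained_fraction_reporting(self, size, expected, rng):
        from pelletchem.selection import SPAResult

        result = SPAResult(
            selected_indices=np.arange(size),
            selected_nm=None,
            rmsev_by_size={size: 1.0},
            chosen_size=size,
            start_index=0,
            chain=list(range(size)),
        )
        assert result.retained_fraction(216) == expected

    def test_n_max_lowered_with_warning(self, rng):
        X = rng.normal(size=(8, 20))
        y = rng.normal(size=8)
        with pytest.warns(UserWarning, match="lowered"):
            spa_select(X, y, X, y, n_min=2, n_max=15)

    def test_informative_bands_recovered_at_low_noise(self):
        # smooth random spectra; y depends on exactly six known bands.
        # At vanishing noise the selected set must land within one SG window
        # of every informative wavelength.
        rng = np.random.default_rng(11)
        wl = np.linspace(958.0, 1683.0, 120)
        bump_centers = np.linspace(970.0, 1670.0, 30)
        bumps = np.exp(-0.5 * ((wl[None, :] - bump_centers[:, None]) / 15.0) ** 2)
        X = rng.uniform(0.0, 1.0, size=(80, 30)) @ bumps
        informative = [int(np.argmin(np.abs(wl - c)))
                       for c in (1000.0, 1120.0, 1240.0, 1360.0, 1480.0, 1600.0)]
        y = X[:, informative] @ rng.uniform(1.0, 2.0, size=6)
        y += rng.normal(scale=1e-8, size=80)
        result = spa_select(X[:60], y[:60], X[60:], y[60:], n_min=5, n_max=20,
                            wavelengths=wl)
        window_nm = 11 * (wl[1] - wl[0]) / 2  # half an SG window
        for idx in informative:
            assert np.min(np.abs(result.selected_nm - wl[idx])) <= window_nm

    def test_selector_estimator_interface(self, rng):
        X = rng.normal(size=(40, 10))
        y = X[:, [2, 5]].sum(axis=1) + rng.normal(scale=0.05, size=40)
        sel = SPASelector(n_min=2, n_max=4).fit(X, y)
        mask = sel.get_support()
        assert mask.sum() == sel.result_.chosen_size
        assert sel.transform(X).shape == (40, mask.sum())


class TestCars:
    def _informative(self, rng, m=60, n=40):
        beta = np.zeros(n)
        informative = [5, 12, 20, 33]
        beta[informative] = [2.0, -1.5, 1.0, 2.5]
        X = rng.normal(size=(m, n))
        y = X @ beta + rng.normal(scale=0.1, size=m)
        return X, y, informative

    def test_deterministic_under_seed(self, rng):
        X, y, _ = self._informative(rng)
        a = cars_select(X, y, n_runs=8, cv_folds=4, seed=5)
        b = cars_select(X, y, n_runs=8, cv_folds=4, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_informative_bands_survive(self, rng):
        X, y, informative = self._informative(rng)
        selected = cars_select(X, y, n_runs=20, cv_folds=5, seed=1)
        assert set(informative) <= set(selected.tolist())

    def test_pure_noise_offers_no_gain(self, rng):
        from pelletchem.regression import PLSRCalibration
        from pelletchem.selection import _pls_cv_rmse

        X = rng.normal(size=(50, 30))
        y = rng.normal(size=50)
        selected = cars_select(X, y, n_runs=10, cv_folds=5, seed=2)
        r = np.random.default_rng(0)
        rmse_sel = _pls_cv_rmse(X, y, selected, 5, 5, r)
        r = np.random.default_rng(0)
        rmse_all = _pls_cv_rmse(X, y, np.arange(30), 5, 5, r)
        assert rmse_sel > 0.5 * np.std(y)  # no material structure discovered
        assert rmse_sel < 2.0 * rmse_all
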