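"""Wavelength selection: successive projections algorithm (SPA) and
competitive adaptive reweighted sampling (CARS).

SPA is a forward selector built for collinear spectra: starting from one
band, it repeatedly projects every unselected band onto the orthogonal
complement of the span of the already-selected bands and appends the band
with the largest projected norm, so each new wavelength carries the most
information not already explained.  Chains are grown from every possible
start band; for every (start, subset size) an ordinary multiple linear
regression is fitted on the calibration set and scored by RMSE on a
validation set, and the global minimizer wins.  Subset sizes are scanned
between ``n_min`` and ``n_max`` (default 5..50).

The validation set defaults to an internal SPXY 3:1 sub-split of the
calibration set, so the held-out prediction set is never touched during
selection.

CARS is the optional Monte-Carlo alternative: each run subsamples the
calibration rows, fits a PLS model, ranks bands by |regression coefficient|,
shrinks the retained set by an exponentially decreasing function plus
adaptive reweighted sampling, and scores the retained subset by k-fold
cross-validated RMSE; the best-scoring subset over all runs is returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .partition import spxy_split
from .regression import PLSRCalibration

_RANK_TOL = 1e-10


def spa_project_chain(X: np.ndarray, start_index: int, chain_length: int) -> list[int]:
    """Grow one SPA chain of band indices by successive orthogonal projections.

    ``X`` must have mean-centered columns (the selector handles centering).
    The chain may be truncated with a warning once every remaining projected
    norm falls below 1e-10 (rank exhausted).
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    if not 0 <= start_index < n:
        raise ValueError(f"start_index {start_index} out of range for {n} bands")
    if chain_length > min(m - 1, n):
        raise ValueError(
            f"chain_length {chain_length} exceeds min(m-1, n) = {min(m - 1, n)}"
        )
    P = X.copy()
    chain = [start_index]
    alive = np.ones(n, dtype=bool)
    alive[start_index] = False
    for _ in range(chain_length - 1):
        last = P[:, chain[-1]]
        nn = float(last @ last)
        if nn < _RANK_TOL**2:
            warnings.warn("SPA chain truncated: projected norms exhausted")
            break
        # deflate every column by its projection onto the last selected one
        coeffs = (last @ P) / nn
        P = P - np.outer(last, coeffs)
        P[:, chain[-1]] = last  # keep the selected column intact for bookkeeping
        norms = np.linalg.norm(P, axis=0)
        norms[~alive] = -1.0
        best = int(np.argmax(norms))
        if norms[best] < _RANK_TOL:
            warnings.warn("SPA chain truncated: projected norms exhausted")
            break
        chain.append(best)
        alive[best] = False
    return chain


def _mlr_rmse(X_cal, y_cal, X_val, y_val, cols) -> float:
    """Validation RMSE of an intercept MLR on the given columns."""
    A = np.column_stack([np.ones(X_cal.shape[0]), X_cal[:, cols]])
    beta, *_ = np.linalg.lstsq(A, y_cal, rcond=None)
    pred = np.column_stack([np.ones(X_val.shape[0]), X_val[:, cols]]) @ beta
    return float(np.sqrt(np.mean((pred - y_val) ** 2)))


@dataclass
class SPAResult:
    """Outcome of an exhaustive SPA scan."""

    selected_indices: np.ndarray          # sorted, for reporting
    selected_nm: np.ndarray | None
    rmsev_by_size: dict[int, float]       # size -> best validation RMSE
    chosen_size: int
    start_index: int                      # start band of the winning chain
    chain: list[int] = field(default_factory=list)  # winning chain, selection order

    @property
    def rmsev(self) -> float:
        return self.rmsev_by_size[self.chosen_size]

    def retained_fraction(self, n_bands: int) -> float:
        """Share of bands kept, in %, reported to 2 decimals."""
        return round(100.0 * self.chosen_size / n_bands, 2)

    def report(self, wavelengths=None):
        """(rank, band_index, wavelength_nm) table in selection order."""
        import pandas as pd

        order = list(self.chain)
        if wavelengths is not None:
            nm = np.asarray(wavelengths, dtype=float)[order]
        elif self.selected_nm is not None:
            by_index = dict(zip(self.selected_indices, self.selected_nm))
            nm = [by_index[i] for i in order]
        else:
            nm = [np.nan] * len(order)
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(order) + 1),
                "band_index": order,
                "wavelength_nm": nm,
            }
        )


def spa_select(
    X_cal,
    y_cal,
    X_val,
    y_val,
    n_min: int = 5,
    n_max: int = 50,
    wavelengths=None,
) -> SPAResult:
    """Exhaustive SPA: all start bands x all sizes in [n_min, n_max].

    For every start band a projection chain of length ``n_max`` is grown on
    the column-centered calibration spectra; every prefix of length
    ``n_min..n_max`` is scored by the validation RMSE of an MLR model fitted
    on the calibration set.  The (start, size) pair with minimal validation
    RMSE wins; ties prefer smaller sizes, then lower start indices.
    """
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_val = np.asarray(y_val, dtype=float).ravel()
    m, n = X_cal.shape
    if n_min < 1 or n_min > n_max:
        raise ValueError("need 1 <= n_min <= n_max")
    cap = min(m - 1, n)
    if n_max > cap:
        warnings.warn(f"n_max lowered from {n_max} to {cap} (rank limit)")
        n_max = cap
        n_min = min(n_min, n_max)
    means = X_cal.mean(axis=0)
    Xc = X_cal - means

    sizes = range(n_min, n_max + 1)
    best_by_size: dict[int, tuple[float, int, list[int]]] = {}
    for start in range(n):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rank truncation handled below
            chain = spa_project_chain(Xc, start, n_max)
        for size in sizes:
            if size > len(chain):
                break
            cols = chain[:size]
            r = _mlr_rmse(X_cal, y_cal, X_val, y_val, cols)
            cur = best_by_size.get(size)
            if cur is None or r < cur[0]:
                best_by_size[size] = (r, start, cols)
    if not best_by_size:
        raise RuntimeError("SPA produced no candidate subsets")
    rmsev_by_size = {s: best_by_size[s][0] for s in sorted(best_by_size)}
    chosen_size = min(rmsev_by_size, key=lambda s: (rmsev_by_size[s], s))
    _, start, cols = best_by_size[chosen_size]
    idx = np.array(sorted(cols))
    nm = None if wavelengths is None else np.asarray(wavelengths, dtype=float)[idx]
    return SPAResult(
        selected_indices=idx,
        selected_nm=nm,
        rmsev_by_size=rmsev_by_size,
        chosen_size=chosen_size,
        start_index=start,
        chain=list(cols),
    )


class SPASelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping the exhaustive SPA scan.

    When no explicit validation set is passed to :meth:`fit`, an internal
    SPXY split (``val_fraction`` of the rows) provides it.
    """

    def __init__(self, n_min: int = 5, n_max: int = 50, val_fraction: float = 0.25):
        self.n_min = n_min
        self.n_max = n_max
        self.val_fraction = val_fraction

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X_val is None:
            # internal SPXY sub-split: larger block trains the MLRs, the
            # held-back block supplies the validation RMSE
            split = spxy_split(X, y, cal_fraction=1 - self.val_fraction)
            train_idx = np.asarray(split.calibration_ids, dtype=int)
            val_idx = np.asarray(split.prediction_ids, dtype=int)
            X_tr, y_tr = X[train_idx], y[train_idx]
            X_val, y_val = X[val_idx], y[val_idx]
        else:
            X_tr, y_tr = X, y
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val, dtype=float).ravel()
        self.result_ = spa_select(
            X_tr, y_tr, X_val, y_val, n_min=self.n_min, n_max=self.n_max
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "result_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.result_.selected_indices] = True
        return mask


# ---------------------------------------------------------------------------
# CARS

def _edf_ratio(run: int, n_runs: int, n_vars: int) -> float:
    """Exponentially decreasing retained-variable ratio (1 -> 2/n over runs)."""
    if n_runs == 1:
        return 1.0
    k = np.log(n_vars / 2.0) / (n_runs - 1)
    return float(np.exp(k) * np.exp(-k * (run + 1)))


def _pls_cv_rmse(X, y, cols, cv_folds: int, max_lv: int, rng) -> float:
    """k-fold CV RMSE of a fixed-LV PLS model on the given columns."""
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=int(rng.integers(2**31)))
    sq = 0.0
    for tr, te in kf.split(X):
        lv = min(max_lv, len(tr) - 1, len(cols))
        model = PLSRCalibration(n_components=lv).fit(X[np.ix_(tr, cols)], y[tr])
        pred = model.predict(X[np.ix_(te, cols)])
        sq += float(np.sum((pred - y[te]) ** 2))
    return float(np.sqrt(sq / len(y)))


def cars_select(
    X_cal,
    y_cal,
    n_runs: int = 50,
    cv_folds: int = 10,
    seed: int | np.random.Generator = 0,
    max_lv: int = 10,
    sample_fraction: float = 0.8,
) -> np.ndarray:
    """Competitive adaptive reweighted sampling; returns sorted band indices.

    Deterministic given ``seed``.  Runs whose retained subset degenerates
    (fewer than 2 bands, or rank-deficient for the PLS) are skipped with a
    warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X_cal, dtype=float)
    y = np.asarray(y_cal, dtype=float).ravel()
    m, n = X.shape
    retained = np.arange(n)
    best_rmse = np.inf
    best_subset = retained.copy()
    n_sample = max(2, int(round(sample_fraction * m)))
    for run in range(n_runs):
        rows = rng.choice(m, size=n_sample, replace=False)
        lv = min(max_lv, n_sample - 1, len(retained))
        try:
            model = PLSRCalibration(n_components=lv).fit(X[np.ix_(rows, retained)], y[rows])
        except ValueError as exc:
            warnings.warn(f"CARS run {run} skipped: {exc}")
            continue
        weights = np.abs(model.coef_)
        if weights.sum() == 0:
            warnings.warn(f"CARS run {run} skipped: zero coefficients")
            continue
        n_keep = max(2, int(round(_edf_ratio(run, n_runs, n) * n)))
        n_keep = min(n_keep, len(retained))
        # enforced reduction: top |coef| bands survive
        order = np.argsort(weights)[::-1]
        forced = retained[order[:n_keep]]
        forced_w = weights[order[:n_keep]]
        # adaptive reweighted sampling among the survivors
        picks = rng.choice(forced, size=n_keep, replace=True, p=forced_w / forced_w.sum())
        subset = np.unique(picks)
        if len(subset) < 2:
            warnings.warn(f"CARS run {run} skipped: degenerate subset")
            continue
        retained = subset
        r = _pls_cv_rmse(X, y, retained, cv_folds, max_lv, rng)
        if r < best_rmse:
            best_rmse = r
            best_subset = retained.copy()
    return np.sort(best_subset)


class CARSSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping :func:`cars_select`."""

    def __init__(
        self,
        n_runs: int = 50,
        cv_folds: int = 10,
        seed: int = 0,
        max_lv: int = 10,
        sample_fraction: float = 0.8,
    ):
        self.n_runs = n_runs
        self.cv_folds = cv_folds
        self.seed = seed
        self.max_lv = max_lv
        self.sample_fraction = sample_fraction

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.selected_indices_ = cars_select(
            X,
            y,
            n_runs=self.n_runs,
            cv_folds=self.cv_folds,
            seed=self.seed,
            max_lv=self.max_lv,
            sample_fraction=self.sample_fraction,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "selected_indices_")
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_indices_] = True
        return mask
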