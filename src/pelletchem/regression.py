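"""Calibration models: PLS1 regression and principal-component MLR.

Both estimators follow the scikit-learn API and center ``X`` and ``y``
internally (independently of any mean-centering pre-processing step, so the
pre-processing chain and the model never double-count the centering).

``PLSRCalibration`` implements single-response PLS via NIPALS with deflation
of both ``X`` and ``y``; the number of latent variables is chosen as the
minimizer of leave-one-out cross-validated RMSE on the calibration set
(ties toward fewer components).  ``PCMLRCalibration`` projects onto
principal-component scores (SVD of the column-centered ``X``) and runs
ordinary least squares on the leading ``k`` scores; ``k`` is chosen by the
same LOO-CV criterion by default, with a raw-calibration-RMSE mode
(1% relative minimum improvement stop) available for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int):
    """NIPALS PLS1 on centered data; returns weight/loading matrices W, P, q."""
    X = Xc.copy()
    y = yc.copy()
    n = X.shape[1]
    W = np.zeros((n, n_components))
    P = np.zeros((n, n_components))
    q = np.zeros(n_components)
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-12:  # y fully deflated / rank exhausted
            return W[:, :a], P[:, :a], q[:a]
        w /= norm
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            return W[:, :a], P[:, :a], q[:a]
        p = X.T @ t / tt
        q[a] = float(y @ t) / tt
        X = X - np.outer(t, p)
        y = y - q[a] * t
        W[:, a] = w
        P[:, a] = p
    return W, P, q


def _pls1_coefs(W: np.ndarray, P: np.ndarray, q: np.ndarray, k: int) -> np.ndarray:
    """Regression vector in original X space using the first k latent variables."""
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


class PLSRCalibration(RegressorMixin, BaseEstimator):
    """PLS1 regression with LOO-CV latent-variable selection.

    Parameters
    ----------
    max_lv : int, default 20
        Largest latent-variable count examined.
    n_components : int, optional
        Fix the LV count instead of selecting by LOO-CV.

    Attributes
    ----------
    n_components_ : selected LV count
    coef_, intercept_ : regression vector and offset on the input band space
    cv_rmse_ : LOO-CV RMSE for 1..max_lv (None when n_components was fixed)
    """

    def __init__(self, max_lv: int = 20, n_components: int | None = None):
        self.max_lv = max_lv
        self.n_components = n_components

    def _fit_path(self, X, y, n_comp):
        x_mean = X.mean(axis=0)
        y_mean = float(np.mean(y))
        W, P, q = _nipals_pls1(X - x_mean, y - y_mean, n_comp)
        return x_mean, y_mean, W, P, q

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        m, n = X.shape
        if np.std(y) == 0:
            raise ValueError("zero-variance response")
        limit = min(self.max_lv, m - 1, n)
        if self.n_components is not None:
            k = min(self.n_components, limit)
            self.cv_rmse_ = None
        else:
            if m <= self.max_lv:
                warnings.warn(f"max_lv reduced to {limit} (only {m} samples)")
            press = np.zeros(limit)
            counts = np.zeros(limit)
            for i in range(m):
                keep = np.arange(m) != i
                xm, ym, W, P, q = self._fit_path(X[keep], y[keep], limit)
                for a in range(1, W.shape[1] + 1):
                    b = _pls1_coefs(W, P, q, a)
                    pred = float((X[i] - xm) @ b) + ym
                    press[a - 1] += (pred - y[i]) ** 2
                    counts[a - 1] += 1
            valid = counts == m
            rmse = np.full(limit, np.inf)
            rmse[valid] = np.sqrt(press[valid] / m)
            self.cv_rmse_ = rmse
            k = int(np.argmin(rmse)) + 1  # argmin -> first minimum -> fewer LVs
        xm, ym, W, P, q = self._fit_path(X, y, k)
        k = min(k, W.shape[1])
        b = _pls1_coefs(W, P, q, k)
        self.n_components_ = k
        self.coef_ = b
        self.intercept_ = ym - float(xm @ b)
        self.x_mean_ = xm
        self.fitted_values_ = X @ b + self.intercept_
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


class PCMLRCalibration(RegressorMixin, BaseEstimator):
    """Principal-component multiple linear regression.

    OLS of the centered response on the leading ``k`` PCA score columns of
    the column-centered ``X``; ``k`` chosen by LOO-CV RMSE
    (``selection="loo"``, default) or by calibration RMSE with a 1% relative
    minimum-improvement stopping rule (``selection="rmsec"``).
    """

    def __init__(
        self,
        max_pc: int = 50,
        n_components: int | None = None,
        selection: str = "loo",
    ):
        self.max_pc = max_pc
        self.n_components = n_components
        self.selection = selection

    @staticmethod
    def _pc_coefs(X, y, k):
        """Regression vector/intercept for k PCs via SVD of centered X."""
        xm = X.mean(axis=0)
        ym = float(np.mean(y))
        U, s, Vt = np.linalg.svd(X - xm, full_matrices=False)
        rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
        k = min(k, rank)
        T = U[:, :k] * s[:k]  # orthogonal score columns
        gamma = T.T @ (y - ym) / (s[:k] ** 2)  # per-score OLS, scores orthogonal
        b = Vt[:k].T @ gamma
        return b, ym - float(xm @ b), rank

    def _cv_curve(self, X, y, limit):
        m = X.shape[0]
        press = np.zeros(limit)
        for i in range(m):
            keep = np.arange(m) != i
            Xi, yi = X[keep], y[keep]
            xm = Xi.mean(axis=0)
            ym = float(np.mean(yi))
            U, s, Vt = np.linalg.svd(Xi - xm, full_matrices=False)
            rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
            kk = min(limit, rank)
            T = U[:, :kk] * s[:kk]
            gamma = T.T @ (yi - ym) / (s[:kk] ** 2)
            z = Vt[:kk] @ (X[i] - xm)  # left-out sample's scores
            cum = ym + np.cumsum(gamma * z)
            preds = np.full(limit, cum[-1] if kk else ym)
            preds[:kk] = cum
            press += (preds - y[i]) ** 2
        return np.sqrt(press / m)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        m, n = X.shape
        if m <= 2:
            raise ValueError("need more than 2 calibration samples")
        if np.std(y) == 0:
            raise ValueError("zero-variance response")
        limit = min(self.max_pc, m - 1, n)
        if self.n_components is not None:
            if self.n_components > limit:
                warnings.warn(f"n_components capped at {limit}")
            k = min(self.n_components, limit)
            self.cv_rmse_ = None
        elif self.selection == "loo":
            self.cv_rmse_ = self._cv_curve(X, y, limit)
            k = int(np.argmin(self.cv_rmse_)) + 1
        elif self.selection == "rmsec":
            self.cv_rmse_ = None
            k = 1
            prev = None
            for kk in range(1, limit + 1):
                b, b0, _ = self._pc_coefs(X, y, kk)
                rmse = float(np.sqrt(np.mean((X @ b + b0 - y) ** 2)))
                if prev is not None and rmse > prev * (1 - 0.01):
                    break
                prev, k = rmse, kk
        else:
            raise ValueError(f"unknown selection mode {self.selection!r}")
        b, b0, rank = self._pc_coefs(X, y, k)
        self.n_components_ = min(k, rank)
        self.coef_ = b
        self.intercept_ = b0
        self.fitted_values_ = X @ b + b0
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


# ---------------------------------------------------------------------------
# evaluation

@dataclass
class ModelReport:
    """R2/RMSE summary on calibration and prediction sets (y units = %)."""

    r2_cal: float | None
    rmsec: float
    r2_pred: float | None
    rmsep: float
    n_components: int
    r2_cal_corr: float | None = None  # squared Pearson correlation variants
    r2_pred_corr: float | None = None

    def to_row(self) -> dict:
        return {
            "Par": self.n_components,
            "R2_cal": self.r2_cal,
            "RMSEC": self.rmsec,
            "R2_pred": self.r2_pred,
            "RMSEP": self.rmsep,
        }


def r_squared(observed, predicted) -> float | None:
    """R2 = 1 - SS_res/SS_tot about the observed mean; None when SS_tot = 0."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return None
    return 1.0 - float(np.sum((observed - predicted) ** 2)) / ss_tot


def rmse(observed, predicted) -> float:
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def _corr2(observed, predicted) -> float | None:
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if np.std(o) == 0 or np.std(p) == 0:
        return None
    return float(np.corrcoef(o, p)[0, 1] ** 2)


def evaluate(model, X_cal, y_cal, X_pred, y_pred) -> ModelReport:
    """Score a fitted model on calibration and prediction sets."""
    y_cal = np.asarray(y_cal, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if len(y_cal) == 0 or len(y_pred) == 0:
        raise ValueError("evaluation sets must be nonempty")
    cal_hat = model.predict(X_cal)
    pred_hat = model.predict(X_pred)
    return ModelReport(
        r2_cal=r_squared(y_cal, cal_hat),
        rmsec=rmse(y_cal, cal_hat),
        r2_pred=r_squared(y_pred, pred_hat),
        rmsep=rmse(y_pred, pred_hat),
        n_components=getattr(model, "n_components_", None)
        or getattr(model, "n_components", 0),
        r2_cal_corr=_corr2(y_cal, cal_hat),
        r2_pred_corr=_corr2(y_pred, pred_hat),
    )


def fit_plsr(X_cal, y_cal, max_lv: int = 20) -> PLSRCalibration:
    """Fit PLS1 with LOO-CV latent-variable selection."""
    return PLSRCalibration(max_lv=max_lv).fit(np.asarray(X_cal, float), y_cal)


def fit_pcmlr(X_cal, y_cal, max_pc: int = 50) -> PCMLRCalibration:
    """Fit PC-MLR with LOO-CV principal-component selection."""
    return PCMLRCalibration(max_pc=max_pc).fit(np.asarray(X_cal, float), y_cal)
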