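"""Spectral pre-treatments: mean centering, SNV, Savitzky-Golay second
derivative and multiplicative scatter correction.

All four are exposed both as scikit-learn transformers (composable with
``sklearn.pipeline.Pipeline``) and as thin module-level functions.  Fitted
statistics (column means for MC, the reference spectrum for MSC) are learned
only from calibration rows and reused verbatim on prediction rows and on
image pixels — the transformers enforce this through the usual fit/transform
split.

SNV standardizes each spectrum to mean 0, sd 1 (n-1 denominator), removing
additive offsets and multiplicative scatter per spectrum.  MSC regresses each
spectrum on a reference (default: calibration mean spectrum) as
``x ~ a + b * ref`` and corrects to ``(x - a) / b``.  The derivative is a
Savitzky-Golay second derivative taken with respect to band index, with
polynomial edge handling so the output keeps the band count.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.pipeline import Pipeline
from sklearn.utils.validation import check_is_fitted

_B_TOL = 1e-12  # minimum |slope| for MSC correction


def _as_2d(X) -> tuple[np.ndarray, bool]:
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        return arr[np.newaxis, :], True
    if arr.ndim != 2:
        raise ValueError(f"expected 1-D spectrum or 2-D table, got ndim={arr.ndim}")
    return arr, False


def _like(result: np.ndarray, template, squeeze: bool):
    if squeeze:
        result = result[0]
    if isinstance(template, pd.DataFrame):
        return pd.DataFrame(result, index=template.index, columns=template.columns)
    if isinstance(template, pd.Series):
        return pd.Series(result, index=template.index)
    return result


class MeanCenterer(TransformerMixin, BaseEstimator):
    """Subtract per-band calibration means from every spectrum."""

    def fit(self, X, y=None):
        arr, _ = _as_2d(X)
        if arr.shape[0] == 1:
            warnings.warn("mean centering fitted on a single spectrum: it will map to zero")
        self.means_ = arr.mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        arr, squeeze = _as_2d(X)
        return _like(arr - self.means_, X, squeeze)


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: per-spectrum (x - mean) / sd, sd with n-1."""

    def fit(self, X, y=None):
        return self

    def __sklearn_is_fitted__(self) -> bool:
        return True  # stateless

    def transform(self, X):
        arr, squeeze = _as_2d(X)
        sd = arr.std(axis=1, ddof=1)
        if np.any(sd == 0) or np.any(~np.isfinite(sd)):
            raise ValueError("SNV undefined for constant spectra (sd = 0)")
        out = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, np.newaxis]
        return _like(out, X, squeeze)


class MSC(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against a reference spectrum.

    Parameters
    ----------
    reference : array-like, optional
        Fixed reference spectrum.  Default: mean spectrum of the fit data.
    """

    def __init__(self, reference=None):
        self.reference = reference

    def fit(self, X, y=None):
        arr, _ = _as_2d(X)
        if self.reference is not None:
            ref = np.asarray(self.reference, dtype=float)
            if ref.shape != (arr.shape[1],):
                raise ValueError("reference length must equal band count")
            self.reference_ = ref
        else:
            self.reference_ = arr.mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "reference_")
        arr, squeeze = _as_2d(X)
        ref = self.reference_
        if arr.shape[1] != ref.shape[0]:
            raise ValueError("band count differs from fitted reference")
        # per-spectrum least squares x ~ a + b*ref, closed form
        ref_c = ref - ref.mean()
        denom = float(ref_c @ ref_c)
        if denom == 0:
            raise ValueError("MSC reference is constant")
        b = (arr - arr.mean(axis=1, keepdims=True)) @ ref_c / denom
        if np.any(np.abs(b) < _B_TOL):
            raise ValueError("MSC slope |b| below tolerance for at least one spectrum")
        a = arr.mean(axis=1) - b * ref.mean()
        out = (arr - a[:, np.newaxis]) / b[:, np.newaxis]
        return _like(out, X, squeeze)


class SavitzkyGolayDerivative(TransformerMixin, BaseEstimator):
    """Savitzky-Golay derivative along the band axis (default: 2nd derivative).

    Derivatives are taken with respect to band *index* (near-uniform band
    spacing makes the nm scaling a constant factor).  Edges are handled by
    polynomial extrapolation so the output length equals the input length.
    """

    def __init__(self, window: int = 11, polyorder: int = 2, deriv: int = 2):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv

    def fit(self, X, y=None):
        return self

    def __sklearn_is_fitted__(self) -> bool:
        return True  # stateless

    def transform(self, X):
        arr, squeeze = _as_2d(X)
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and greater than polyorder")
        if arr.shape[1] < self.window:
            raise ValueError(
                f"need at least {self.window} bands for window={self.window}, "
                f"got {arr.shape[1]}"
            )
        out = savgol_filter(
            arr, self.window, self.polyorder, deriv=self.deriv, axis=1, mode="interp"
        )
        return _like(out, X, squeeze)


# ---------------------------------------------------------------------------
# chains

_STEP_FACTORIES = {
    "mc": MeanCenterer,
    "snv": SNV,
    "d2": SavitzkyGolayDerivative,
    "msc": MSC,
}


def build_chain(steps, **step_params) -> Pipeline:
    """Build a pre-processing Pipeline from step names.

    ``steps`` is a list drawn from {"mc", "snv", "d2", "msc"} (case-insensitive)
    or a string like ``"snv"``, ``"snv+d2"``, ``"none"``/``"raw"``/``""``.
    Keyword arguments prefixed by the step name are forwarded, e.g.
    ``d2__window=9``.
    """
    if isinstance(steps, str):
        steps = [] if steps.lower() in ("", "none", "raw") else steps.lower().split("+")
    names = [s.lower() for s in steps]
    built = []
    for name in names:
        if name not in _STEP_FACTORIES:
            raise ValueError(f"unknown pre-processing step {name!r}")
        params = {
            k.split("__", 1)[1]: v
            for k, v in step_params.items()
            if k.startswith(name + "__")
        }
        built.append((name, _STEP_FACTORIES[name](**params)))
    if not built:
        built = [("identity", FunctionTransformerIdentity())]
    return Pipeline(built)


class FunctionTransformerIdentity(TransformerMixin, BaseEstimator):
    """No-op placeholder so an empty chain is still a valid Pipeline."""

    def fit(self, X, y=None):
        return self

    def __sklearn_is_fitted__(self) -> bool:
        return True  # stateless

    def transform(self, X):
        return X


def chain_steps(chain: Pipeline) -> list[str]:
    """Step names of a chain built by :func:`build_chain` ('' for identity)."""
    return [name for name, _ in chain.steps if name != "identity"]


def chain_state(chain: Pipeline) -> list[dict]:
    """Serializable state (names, params, fitted statistics) of a fitted chain."""
    state = []
    for name, step in chain.steps:
        if name == "identity":
            continue
        entry: dict = {"name": name, "params": step.get_params()}
        if isinstance(step, MeanCenterer):
            entry["means"] = step.means_.tolist()
        elif isinstance(step, MSC):
            entry["params"] = {}
            entry["reference"] = step.reference_.tolist()
        state.append(entry)
    return state


def chain_from_state(state: list[dict]) -> Pipeline:
    """Rebuild a fitted chain from :func:`chain_state` output."""
    steps = []
    for entry in state:
        name = entry["name"]
        step = _STEP_FACTORIES[name](**entry.get("params", {}))
        if name == "mc":
            step.means_ = np.asarray(entry["means"], dtype=float)
        elif name == "msc":
            step.reference_ = np.asarray(entry["reference"], dtype=float)
        steps.append((name, step))
    if not steps:
        steps = [("identity", FunctionTransformerIdentity())]
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# thin functional wrappers

def mean_center(table, fitted_means=None):
    """Mean-center a table; with ``fitted_means`` given, apply stored means."""
    mc = MeanCenterer()
    if fitted_means is None:
        mc.fit(table)
    else:
        mc.means_ = np.asarray(fitted_means, dtype=float)
    return mc.transform(table)


def snv(x):
    """SNV-transform a spectrum or table."""
    return SNV().transform(x)


def msc(table, reference=None):
    """MSC-correct a table (reference defaults to the table's mean spectrum)."""
    return MSC(reference=reference).fit(table).transform(table)


def second_derivative(table, window: int = 11, polyorder: int = 2):
    """Savitzky-Golay second derivative per spectrum."""
    return SavitzkyGolayDerivative(window=window, polyorder=polyorder).transform(table)
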