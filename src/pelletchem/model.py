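"""Bundled calibration model: pre-processing chain, band subset, linear model.

A :class:`CalibrationModel` is what gets transferred from the tabular
calibration stage onto new ROI spectra and onto every pixel of a cube.  It
records the fitted pre-processing chain (with its calibration statistics),
the selected band indices *within the trimmed window*, the model family and
component count, and the regression vector.  Everything is serialized to a
single JSON file so a map rebuilt later uses byte-identical pre-processing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocessing as prep

WAVELENGTH_TOL_NM = 0.5  # bands must match training wavelengths this closely


@dataclass
class CalibrationModel:
    component: str              # response name, e.g. "cellulose"
    family: str                 # "plsr" | "pcmlr"
    chain: object               # fitted pre-processing Pipeline
    wavelengths: np.ndarray     # full trimmed-window band centers (nm)
    band_indices: np.ndarray    # selected indices into `wavelengths`
    n_components: int
    coef: np.ndarray            # on the pre-processed, selected-band space
    intercept: float
    fitted_values: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.band_indices = np.asarray(self.band_indices, dtype=int)
        self.coef = np.asarray(self.coef, dtype=float)
        if len(self.coef) != len(self.band_indices):
            raise ValueError("coefficient length must match selected band count")

    @property
    def selected_nm(self) -> np.ndarray:
        return self.wavelengths[self.band_indices]

    @property
    def name(self) -> str:
        steps = prep.chain_steps(self.chain)
        label = {"plsr": "PLSR", "pcmlr": "PC-MLR"}[self.family]
        parts = [s.upper() for s in steps]
        if len(self.band_indices) < len(self.wavelengths):
            parts.append("SPA")
        parts.append(label)
        return "–".join(parts) if parts else label  # en-dash joined

    # -- prediction ---------------------------------------------------------

    def _align(self, X) -> np.ndarray:
        """Match input bands to training wavelengths within 0.5 nm."""
        if isinstance(X, pd.DataFrame):
            wl = np.asarray(X.columns, dtype=float)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim == 1:
                arr = arr[np.newaxis, :]
            if arr.shape[1] == len(self.wavelengths):
                return arr
            raise ValueError(
                f"input has {arr.shape[1]} bands; model expects "
                f"{len(self.wavelengths)} (pass a DataFrame with nm columns "
                "to align by wavelength)"
            )
        idx = np.searchsorted(wl, self.wavelengths)
        idx = np.clip(idx, 0, len(wl) - 1)
        left = np.clip(idx - 1, 0, len(wl) - 1)
        idx = np.where(
            np.abs(wl[left] - self.wavelengths) <= np.abs(wl[idx] - self.wavelengths),
            left,
            idx,
        )
        err = np.abs(wl[idx] - self.wavelengths)
        missing = self.wavelengths[err > WAVELENGTH_TOL_NM]
        if missing.size:
            raise ValueError(
                "input is missing trained bands (nm): "
                + ", ".join(f"{w:.2f}" for w in missing[:10])
                + ("..." if missing.size > 10 else "")
            )
        return arr[:, idx]

    def predict(self, X) -> np.ndarray:
        """Chain (fitted statistics) -> band subset -> linear model, in %."""
        arr = self._align(X)
        pre = np.asarray(self.chain.transform(arr), dtype=float)
        sub = pre[:, self.band_indices]
        return sub @ self.coef + self.intercept

    # -- persistence --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "family": self.family,
            "chain": prep.chain_state(self.chain),
            "wavelengths": self.wavelengths.tolist(),
            "band_indices": self.band_indices.tolist(),
            "n_components": int(self.n_components),
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(
            component=d["component"],
            family=d["family"],
            chain=prep.chain_from_state(d["chain"]),
            wavelengths=np.asarray(d["wavelengths"], dtype=float),
            band_indices=np.asarray(d["band_indices"], dtype=int),
            n_components=int(d["n_components"]),
            coef=np.asarray(d["coef"], dtype=float),
            intercept=float(d["intercept"]),
        )

    @classmethod
    def load(cls, path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
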