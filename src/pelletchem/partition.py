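"""SPXY sample-set partitioning (Kennard-Stone on joint x-y distances).

Calibration/prediction splits for spectral calibration should cover both the
spectral space and the response space.  SPXY combines the two: with
Euclidean distances ``d_x`` on spectra and ``d_y`` on the (standardized)
response block, the joint metric is::

    d_xy(p, q) = d_x(p, q) / max d_x  +  d_y(p, q) / max d_y

Kennard-Stone selection on ``d_xy`` then seeds the calibration set with the
mutually most-distant pair and grows it by repeatedly adding the sample with
the largest minimum joint distance to the already-selected set.  The
remainder becomes the prediction set.  The procedure is deterministic; ties
break toward the lowest sample index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator


@dataclass
class SplitResult:
    """Disjoint calibration/prediction id lists from one SPXY run."""

    calibration_ids: list
    prediction_ids: list
    ratio: float

    def __post_init__(self) -> None:
        overlap = set(self.calibration_ids) & set(self.prediction_ids)
        if overlap:
            raise ValueError(f"calibration and prediction sets overlap: {overlap}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(i, "cal") for i in self.calibration_ids] + [
            (i, "pred") for i in self.prediction_ids
        ]
        return pd.DataFrame(rows, columns=["sample_id", "set"])

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def load(cls, path) -> "SplitResult":
        df = pd.read_csv(path)
        cal = df.loc[df["set"] == "cal", "sample_id"].tolist()
        pred = df.loc[df["set"] == "pred", "sample_id"].tolist()
        total = len(cal) + len(pred)
        return cls(cal, pred, len(cal) / total if total else 0.0)


def _joint_distances(X: np.ndarray, Y: np.ndarray, standardize_y: bool) -> np.ndarray:
    dx = squareform(pdist(X, metric="euclidean"))
    if standardize_y:
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Y = (Y - Y.mean(axis=0)) / sd
    dy = squareform(pdist(Y, metric="euclidean"))
    mx, my = dx.max(), dy.max()
    if mx == 0 and my == 0:
        raise ValueError("all samples identical in both x and y")
    d = np.zeros_like(dx)
    if mx == 0:
        warnings.warn("all spectra identical: x-distance term dropped")
    else:
        d += dx / mx
    if my == 0:
        warnings.warn("all responses identical: y-distance term dropped")
    else:
        d += dy / my
    return d


def _kennard_stone(d: np.ndarray, n_select: int) -> list[int]:
    m = d.shape[0]
    # seed: pair at maximal distance; np.argmax takes the first (lowest-index) max
    seed = int(np.argmax(d))
    i, j = divmod(seed, m)
    selected = [min(i, j), max(i, j)]
    remaining = [k for k in range(m) if k not in selected]
    min_d = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_select and remaining:
        cand = remaining[int(np.argmax(min_d[remaining]))]
        selected.append(cand)
        remaining.remove(cand)
        min_d = np.minimum(min_d, d[cand])
    return selected


class SPXYSplitter(BaseEstimator):
    """SPXY calibration/prediction splitter.

    Parameters
    ----------
    cal_fraction : float, default 0.75
        Calibration share; the calibration count is ``round(m * cal_fraction)``
        (a 3:1 split of 148 samples gives 111 calibration / 37 prediction).
    standardize_y : bool, default True
        z-score the response columns before computing ``d_y`` so components
        on different scales contribute comparably.
    """

    def __init__(self, cal_fraction: float = 0.75, standardize_y: bool = True):
        self.cal_fraction = cal_fraction
        self.standardize_y = standardize_y

    def split(self, X, Y) -> SplitResult:
        ids = list(X.index) if isinstance(X, pd.DataFrame) else list(range(len(X)))
        Xa = np.asarray(X, dtype=float)
        Ya = np.asarray(Y, dtype=float)
        if Ya.ndim == 1:
            Ya = Ya[:, np.newaxis]
        if Xa.shape[0] != Ya.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        m = Xa.shape[0]
        if m < 3:
            raise ValueError("SPXY needs at least 3 samples")
        if not 0 < self.cal_fraction < 1:
            raise ValueError("cal_fraction must be in (0, 1)")
        n_cal = int(round(m * self.cal_fraction))
        n_cal = min(max(n_cal, 2), m - 1)
        d = _joint_distances(Xa, Ya, self.standardize_y)
        sel = _kennard_stone(d, n_cal)
        sel_set = set(sel)
        cal_ids = [ids[k] for k in sorted(sel)]
        pred_ids = [ids[k] for k in range(m) if k not in sel_set]
        return SplitResult(cal_ids, pred_ids, self.cal_fraction)


def spxy_split(X, Y, cal_fraction: float = 0.75, standardize_y: bool = True) -> SplitResult:
    """Functional wrapper over :class:`SPXYSplitter`."""
    return SPXYSplitter(cal_fraction, standardize_y).split(X, Y)
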