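"""Pixel-level chemical maps: model transfer, mask-aware median filtering,
blue-to-red rendering and per-pellet summaries.

A fitted calibration model is applied to the spectrum of every foreground
pixel of a calibrated, band-trimmed cube; the background stays undefined
(NaN).  Salt-and-pepper noise in the resulting concentration image is
removed with a median filter restricted to the pellet mask, so background
never bleeds into pellet edges.  Maps are rendered on a blue-to-red scale
with the background neutral, one color scale per component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cube import SpectralCube
from .model import CalibrationModel
from .segmentation import ForegroundMask


@dataclass
class ConcentrationMap:
    """Per-pixel predicted concentration (%), NaN outside the mask."""

    values: np.ndarray
    mask: ForegroundMask
    component: str
    n_failed_pixels: int = 0
    per_pellet_means: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.mask.shape:
            raise ValueError("map shape must equal mask shape")

    def summarize(self) -> pd.DataFrame:
        """Per-pellet (8-connected component) mean and pixel count."""
        labels = self.mask.labels()
        rows = []
        for label in range(1, labels.max() + 1):
            sel = (labels == label) & np.isfinite(self.values)
            rows.append(
                {
                    "label": label,
                    "component": self.component,
                    "mean_percent": float(np.mean(self.values[sel])) if sel.any() else np.nan,
                    "n_pixels": int(sel.sum()),
                }
            )
        self.per_pellet_means = pd.DataFrame(rows)
        return self.per_pellet_means


def predict_map(
    cube: SpectralCube, mask: ForegroundMask, model: CalibrationModel
) -> ConcentrationMap:
    """Transfer a calibration model to every foreground pixel.

    Pixels whose pre-processing chain fails (e.g. a constant spectrum under
    SNV) are left NaN and counted in ``n_failed_pixels``.
    """
    if cube.kind != "calibrated":
        raise ValueError("predict_map expects a calibrated cube")
    m = mask.mask
    if m.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    if cube.invalid is not None:
        m = m & ~cube.invalid
    spectra = pd.DataFrame(cube.data[m], columns=cube.wavelengths)
    model._align(spectra.iloc[:1])  # wavelength mismatches must error out here
    values = np.full(cube.shape[:2], np.nan)
    n_failed = 0
    try:
        values[m] = model.predict(spectra)
    except ValueError:
        # fall back to per-pixel application so one bad spectrum cannot
        # void the whole map
        preds = np.full(spectra.shape[0], np.nan)
        for i in range(spectra.shape[0]):
            try:
                preds[i] = model.predict(spectra.iloc[[i]])[0]
            except ValueError:
                n_failed += 1
        values[m] = preds
    return ConcentrationMap(values, mask, model.component, n_failed_pixels=n_failed)


def median_filter_map(cmap: ConcentrationMap, kernel: int = 3) -> ConcentrationMap:
    """Mask-aware median filter: per-pixel median over the kernel
    neighborhood intersected with the foreground mask."""
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 3")
    r = kernel // 2
    vals = np.where(np.isfinite(cmap.values), cmap.values, np.nan)
    padded = np.pad(vals, r, constant_values=np.nan)
    stack = np.stack(
        [
            padded[r + dr : padded.shape[0] - r + dr, r + dc : padded.shape[1] - r + dc]
            for dr in range(-r, r + 1)
            for dc in range(-r, r + 1)
        ]
    )
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            med = np.nanmedian(stack, axis=0)
    out = np.where(cmap.mask.mask & np.isfinite(cmap.values), med, cmap.values)
    return ConcentrationMap(out, cmap.mask, cmap.component, cmap.n_failed_pixels)


def render_map(
    cmap: ConcentrationMap,
    out_path,
    vmin: float | None = None,
    vmax: float | None = None,
    annotate: bool = False,
) -> dict:
    """Render to a PNG-class image: blue-to-red scale, neutral background.

    Returns the metadata written alongside (color-bar limits etc.).
    """
    import json
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = cmap.values[np.isfinite(cmap.values)]
    if finite.size == 0:
        raise ValueError("map has no defined pixels to render")
    lo = float(np.min(finite)) if vmin is None else float(vmin)
    hi = float(np.max(finite)) if vmax is None else float(vmax)
    if hi == lo:
        hi = lo + 1e-9
    colormap = matplotlib.colormaps["jet"].copy()  # blue -> red
    colormap.set_bad(color="0.85")  # neutral background
    fig, ax = plt.subplots(figsize=(5, 4))
    shown = np.ma.masked_invalid(cmap.values)
    im = ax.imshow(shown, cmap=colormap, vmin=lo, vmax=hi)
    fig.colorbar(im, ax=ax, label=f"{cmap.component} (%)")
    ax.set_axis_off()
    ax.set_title(cmap.component)
    if annotate:
        summary = cmap.summarize()
        labels = cmap.mask.labels()
        for _, row in summary.iterrows():
            sel = labels == row["label"]
            rr, cc = np.nonzero(sel)
            ax.text(
                cc.mean(),
                rr.mean(),
                f"{row['mean_percent']:.1f}",
                ha="center",
                va="center",
                fontsize=8,
                color="white",
            )
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    meta = {"component": cmap.component, "vmin": lo, "vmax": hi}
    Path(str(out_path) + ".json").write_text(json.dumps(meta))
    return meta
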