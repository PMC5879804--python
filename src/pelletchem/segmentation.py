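"""Pellet segmentation by single-band thresholding and ROI spectrum extraction.

Pellets sit bright on a dark conveyor in the NIR, so a single threshold on
the band nearest 1196 nm separates foreground from background.  The
threshold is expressed on the normalized 0-1 scale: raw-count cubes are
divided by the 4095 sensor maximum first, calibrated reflectance is compared
directly.  The default 800/4095 ~= 0.195 reproduces the "counts > 800" rule
used with 12-bit line-scan cameras.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .cube import SENSOR_MAX, SpectralCube

DEFAULT_THRESHOLD = 800 / 4095
DEFAULT_BAND_NM = 1196.0


@dataclass
class ForegroundMask:
    """Boolean pellet mask plus the thresholding parameters that produced it."""

    mask: np.ndarray
    threshold_used: float
    band_nm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def labels(self, connectivity: int = 2) -> np.ndarray:
        """Label connected pellets (8-connectivity by default); 0 = background."""
        structure = ndimage.generate_binary_structure(2, connectivity)
        labeled, _ = ndimage.label(self.mask, structure=structure)
        return labeled


def build_mask(
    cube: SpectralCube,
    band_nm: float = DEFAULT_BAND_NM,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    min_component_size: int = 0,
) -> ForegroundMask:
    """Threshold the band nearest ``band_nm``: foreground iff value > threshold.

    ``min_component_size`` optionally drops connected components smaller than
    that many pixels (off by default — plain thresholding is the reference
    behaviour).  Raises if no pellet pixel survives.
    """
    if not (cube.wavelengths[0] <= band_nm <= cube.wavelengths[-1]):
        raise ValueError(
            f"band {band_nm} nm outside cube range "
            f"[{cube.wavelengths[0]:.2f}, {cube.wavelengths[-1]:.2f}]"
        )
    plane = cube.data[:, :, cube.band_index(band_nm)].astype(float)
    if cube.kind == "raw":
        plane = plane / SENSOR_MAX
    mask = plane > threshold
    if cube.invalid is not None:
        mask &= ~cube.invalid
    if min_component_size > 0 and mask.any():
        structure = ndimage.generate_binary_structure(2, 2)
        labeled, n = ndimage.label(mask, structure=structure)
        counts = np.bincount(labeled.ravel())
        small = np.flatnonzero(counts < min_component_size)
        mask &= ~np.isin(labeled, small[small > 0])
    if not mask.any():
        raise ValueError("no sample detected: threshold leaves an empty mask")
    return ForegroundMask(mask, threshold, float(cube.wavelengths[cube.band_index(band_nm)]))


def mean_roi_spectrum(cube: SpectralCube, mask: ForegroundMask) -> np.ndarray:
    """Arithmetic mean spectrum over masked pixels, per band.

    Invalid-flagged pixels are excluded; raises if nothing valid remains.
    """
    m = mask.mask
    if m.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if cube.invalid is not None:
        m = m & ~cube.invalid
    if not m.any():
        raise ValueError("mask selects no valid pixels")
    pixels = cube.data[m]  # (n_pixels, bands)
    return np.nanmean(pixels.astype(float), axis=0)


def per_pellet_spectra(
    cube: SpectralCube, mask: ForegroundMask, connectivity: int = 2
) -> pd.DataFrame:
    """Mean ROI spectrum per connected pellet; index = pellet label."""
    labeled = mask.labels(connectivity)
    rows = {}
    for label in range(1, labeled.max() + 1):
        sub = ForegroundMask(labeled == label, mask.threshold_used, mask.band_nm)
        rows[label] = mean_roi_spectrum(cube, sub)
    return pd.DataFrame.from_dict(rows, orient="index", columns=cube.wavelengths)


def save_mask(mask: ForegroundMask, path) -> None:
    """Export the mask as a portable grayscale PGM image (0/255)."""
    import imageio.v3 as iio

    iio.imwrite(path, (mask.mask * np.uint8(255)))


def append_spectrum(path, sample_id: str, wavelengths, spectrum) -> None:
    """Append one ROI spectrum row to a CSV spectrum table (header on create)."""
    from pathlib import Path

    path = Path(path)
    row = pd.DataFrame(
        [np.asarray(spectrum, dtype=float)],
        index=pd.Index([sample_id], name="sample_id"),
        columns=[f"{w:.2f}" for w in np.asarray(wavelengths, dtype=float)],
    )
    row.to_csv(path, mode="a", header=not path.exists())
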