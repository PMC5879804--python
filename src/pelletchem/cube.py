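"""Hyperspectral cube containers, reflectance calibration and band trimming.

A :class:`SpectralCube` is a ``rows x cols x bands`` array with a strictly
increasing wavelength vector in nm.  Raw cubes hold sensor counts (the
push-broom cameras targeted here saturate at 4095 counts); calibrated cubes
hold reflectance computed from a white and a dark reference frame::

    R = (I_raw - I_dark) / (I_white - I_dark)

Reflectance is deliberately *not* clipped to [0, 1]: clipping would bias the
scatter-correction statistics (SNV/MSC) computed downstream.  Pixels where
the white and dark references coincide are flagged invalid instead of being
silently divided to +/-inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

SENSOR_MAX = 4095  # 12-bit detector full scale

#: default retained spectral window in nm; the noisy front/back instrument
#: ranges outside it are discarded before any chemometrics
DEFAULT_TRIM_NM = (958.0, 1683.0)


@dataclass
class SpectralCube:
    """3-D hyperspectral image: ``data[row, col, band]`` plus wavelengths (nm)."""

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"  # "raw" | "calibrated"
    invalid: np.ndarray | None = field(default=None)  # 2-D bool, True = bad pixel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {len(self.wavelengths)} does not match "
                f"band dimension {self.data.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in ("raw", "calibrated"):
            raise ValueError(f"kind must be 'raw' or 'calibrated', got {self.kind!r}")
        if self.invalid is not None:
            self.invalid = np.asarray(self.invalid, dtype=bool)
            if self.invalid.shape != self.data.shape[:2]:
                raise ValueError("invalid mask shape must equal cube spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, nm: float) -> int:
        """Index of the band center nearest ``nm``; ties go to the lower index."""
        d = np.abs(self.wavelengths - nm)
        return int(np.argmin(d))  # argmin returns first minimum -> lower index


@dataclass
class ReferenceFrame:
    """White or dark reference matching a cube's geometry.

    May be a full ``rows x cols x bands`` recording or a single representative
    line ``cols x bands``; :meth:`as_pixelwise` broadcasts either to the cube.
    """

    data: np.ndarray
    role: str  # "white" | "dark"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("reference frame must be 2-D (cols x bands) or 3-D")
        if self.role not in ("white", "dark"):
            raise ValueError(f"role must be 'white' or 'dark', got {self.role!r}")

    def mean_line(self) -> np.ndarray:
        """Average along the scan axis -> one ``cols x bands`` line."""
        if self.data.ndim == 2:
            return self.data
        return self.data.mean(axis=0)

    def as_pixelwise(self, shape: tuple[int, int, int]) -> np.ndarray:
        """Broadcastable per-pixel reference for a cube of ``shape``."""
        rows, cols, bands = shape
        if self.data.ndim == 3:
            if self.data.shape != shape:
                raise ValueError(
                    f"reference shape {self.data.shape} incompatible with cube {shape}"
                )
            return self.data
        if self.data.shape != (cols, bands):
            raise ValueError(
                f"reference line shape {self.data.shape} incompatible with cube {shape}"
            )
        return self.data[np.newaxis, :, :]


def calibrate(
    raw: SpectralCube,
    white: ReferenceFrame,
    dark: ReferenceFrame,
    *,
    average_references: bool = False,
) -> SpectralCube:
    """Reflectance calibration R = (raw - dark) / (white - dark).

    Parameters
    ----------
    raw
        Raw-count cube (``kind == "raw"``).
    white, dark
        Reference frames with the same band count as the cube.
    average_references
        If True, 3-D references are first averaged along the scan axis into one
        representative line (suppresses reference noise for push-broom data);
        default applies them per pixel.

    Pixels where ``white == dark`` at any band are flagged in ``invalid`` and
    set to NaN at the offending bands rather than left infinite.
    """
    if raw.kind != "raw":
        raise ValueError("calibrate expects a raw cube")
    w = white
    d = dark
    if average_references:
        w = ReferenceFrame(white.mean_line(), "white")
        d = ReferenceFrame(dark.mean_line(), "dark")
    w_arr = w.as_pixelwise(raw.shape)
    d_arr = d.as_pixelwise(raw.shape)
    denom = w_arr - d_arr
    bad = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = (raw.data.astype(float) - d_arr) / denom
    invalid = np.zeros(raw.shape[:2], dtype=bool)
    if np.any(bad):
        refl = np.where(np.broadcast_to(bad, refl.shape), np.nan, refl)
        invalid = np.any(np.broadcast_to(bad, refl.shape), axis=2)
    if raw.invalid is not None:
        invalid |= raw.invalid
    return SpectralCube(refl, raw.wavelengths.copy(), kind="calibrated", invalid=invalid)


def trim_bands(
    cube,
    keep_lo_nm: float = DEFAULT_TRIM_NM[0],
    keep_hi_nm: float = DEFAULT_TRIM_NM[1],
):
    """Retain only bands with ``keep_lo_nm <= lambda <= keep_hi_nm`` (inclusive).

    Accepts a :class:`SpectralCube` or a spectrum table (DataFrame whose
    columns are wavelengths in nm) and returns the same type.
    """
    if not isinstance(cube, SpectralCube):
        return trim_table(cube, keep_lo_nm, keep_hi_nm)
    if keep_lo_nm >= keep_hi_nm:
        raise ValueError("keep_lo_nm must be < keep_hi_nm")
    keep = (cube.wavelengths >= keep_lo_nm) & (cube.wavelengths <= keep_hi_nm)
    if not np.any(keep):
        raise ValueError(
            f"no bands inside [{keep_lo_nm}, {keep_hi_nm}] nm "
            f"(cube covers {cube.wavelengths[0]:.2f}-{cube.wavelengths[-1]:.2f} nm)"
        )
    return replace(cube, data=cube.data[:, :, keep], wavelengths=cube.wavelengths[keep])


def trim_table(
    table,
    keep_lo_nm: float = DEFAULT_TRIM_NM[0],
    keep_hi_nm: float = DEFAULT_TRIM_NM[1],
):
    """Trim a spectrum table (DataFrame with float nm columns) to a window."""
    wl = np.asarray(table.columns, dtype=float)
    if keep_lo_nm >= keep_hi_nm:
        raise ValueError("keep_lo_nm must be < keep_hi_nm")
    keep = (wl >= keep_lo_nm) & (wl <= keep_hi_nm)
    if not np.any(keep):
        raise ValueError(f"no bands inside [{keep_lo_nm}, {keep_hi_nm}] nm")
    return table.loc[:, table.columns[keep]]
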