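"""Synthetic NIR hyperspectral world with known ground truth.

Emulates the measurement chain end to end so every pipeline stage is
testable without instrument data: 256 contiguous bands over
874.41-1733.91 nm, pellet-shaped foreground on a dark conveyor background,
pure-component absorbance built from Gaussian overtone bands at the
literature NIR assignments for cellulose, hemicellulose and lignin, and
concentration statistics matching a realistic pellet survey
(cellulose ~49 +/- 8%, hemicellulose ~18 +/- 4%, lignin ~20 +/- 4%).

Mixing is Beer-Lambert-style log-linear: absorbance is the
concentration-weighted sum of pure spectra plus a baseline, reflectance is
``10**(-A)`` (hence always in (0, 1]).  Optional per-sample multiplicative/
additive scatter (``a + b*x`` with ``b ~ U[0.8, 1.2]``) and additive
Gaussian sensor noise supply the distortions that SNV and MSC exist to
remove.  Raw cubes are quantized to the 12-bit 0..4095 count range using
white/dark reference lines, so reflectance calibration can be inverted to
within one count.

Every artifact is a pure function of (configuration, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cube import SENSOR_MAX, ReferenceFrame, SpectralCube

#: instrument band grid: 256 contiguous bands
WL_MIN_NM = 874.41
WL_MAX_NM = 1733.91
N_BANDS = 256

COMPONENTS = ("cellulose", "hemicellulose", "lignin")

#: concentration statistics (% dry weight): mean, sd, (min, max)
CONCENTRATION_STATS = {
    "cellulose": (49.14, 7.72, (18.94, 64.56)),
    "hemicellulose": (18.42, 3.76, (11.12, 30.98)),
    "lignin": (20.25, 3.57, (13.87, 29.12)),
}

#: NIR overtone/combination band centers shared by all three polymers
SHARED_CENTERS_NM = (1321.0, 1372.0, 1548.0, 1673.0)

#: component-specific band centers (nm); the 1653/1659 vinyl C=C pair is
#: merged to 1656 nm, below the ~3.4 nm band spacing of the grid
COMPONENT_CENTERS_NM = {
    "cellulose": (985.0, 1204.0, 1440.0, 1483.0, 1514.0, 1582.0, 1656.0, 1683.0),
    "hemicellulose": (1109.0, 1197.0, 1416.0, 1429.0, 1622.0),
    "lignin": (1264.0, 1534.0, 1646.0),
}

DEFAULT_BAND_SD_NM = 10.0    # Gaussian band sd; ~24 nm FWHM, typical NIR overtone
DEFAULT_AMPLITUDE = 0.6      # absorbance a.u. at concentration 100%
SHARED_AMPLITUDE = 0.35      # shared bands are weaker per component
BASELINE_ABS = 0.25          # flat matrix absorbance
BACKGROUND_REFL = 0.05       # conveyor-belt reflectance
WHITE_COUNTS = 3900.0
DARK_COUNTS = 60.0


def default_wavelengths() -> np.ndarray:
    return np.linspace(WL_MIN_NM, WL_MAX_NM, N_BANDS)


@dataclass
class ComponentSpectrumSpec:
    """Pure-component absorbance as a sum of Gaussian bands."""

    name: str
    centers_nm: tuple
    widths_nm: tuple
    amplitudes: tuple

    def __post_init__(self) -> None:
        k = len(self.centers_nm)
        if not (len(self.widths_nm) == len(self.amplitudes) == k):
            raise ValueError("centers, widths and amplitudes must have equal length")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")


def default_component_specs(
    band_sd_nm: float = DEFAULT_BAND_SD_NM,
    amplitude: float = DEFAULT_AMPLITUDE,
    shared_amplitude: float = SHARED_AMPLITUDE,
) -> list[ComponentSpectrumSpec]:
    specs = []
    for name in COMPONENTS:
        own = COMPONENT_CENTERS_NM[name]
        centers = own + SHARED_CENTERS_NM
        amps = (amplitude,) * len(own) + (shared_amplitude,) * len(SHARED_CENTERS_NM)
        specs.append(
            ComponentSpectrumSpec(name, centers, (band_sd_nm,) * len(centers), amps)
        )
    return specs


def make_component_spectra(specs, wavelengths) -> np.ndarray:
    """Pure-component absorbance matrix, one row per spec."""
    wl = np.asarray(wavelengths, dtype=float)
    out = np.zeros((len(specs), len(wl)))
    for i, spec in enumerate(specs):
        for c, w, a in zip(spec.centers_nm, spec.widths_nm, spec.amplitudes):
            if not (wl[0] <= c <= wl[-1]):
                raise ValueError(
                    f"band center {c} nm outside wavelength grid "
                    f"[{wl[0]:.2f}, {wl[-1]:.2f}]"
                )
            out[i] += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return out


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must recover."""

    concentrations: pd.DataFrame
    component_centers_nm: dict
    pure_spectra: np.ndarray
    wavelengths: np.ndarray
    noise_sd: float
    scatter: bool
    seed: int
    scatter_slopes: np.ndarray | None = None
    scatter_offsets: np.ndarray | None = None
    # cube-only fields
    mask: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)
    concentration_fields: dict | None = field(default=None, repr=False)
    pellet_means: pd.DataFrame | None = None


def _draw_concentrations(m: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, (mean, sd, (lo, hi)) in CONCENTRATION_STATS.items():
        a, b = (lo - mean) / sd, (hi - mean) / sd
        cols[name] = stats.truncnorm.rvs(
            a, b, loc=mean, scale=sd, size=m, random_state=rng
        )
    df = pd.DataFrame(cols, index=[f"S{i + 1:03d}" for i in range(m)])
    df.index.name = "sample_id"
    # resample the rare rows whose components would sum past a physical total
    bad = df.sum(axis=1) > 99.0
    guard = 0
    while bad.any():
        guard += 1
        if guard > 100:
            raise RuntimeError("could not draw sum-compatible concentrations")
        for name, (mean, sd, (lo, hi)) in CONCENTRATION_STATS.items():
            a, b = (lo - mean) / sd, (hi - mean) / sd
            df.loc[bad, name] = stats.truncnorm.rvs(
                a, b, loc=mean, scale=sd, size=int(bad.sum()), random_state=rng
            )
        bad = df.sum(axis=1) > 99.0
    return df


def _reflectance_from_concentrations(conc: np.ndarray, pure: np.ndarray) -> np.ndarray:
    """conc (m x 3, %) and pure (3 x n) -> reflectance (m x n) in (0, 1]."""
    absorbance = BASELINE_ABS + (conc / 100.0) @ pure
    return 10.0 ** (-absorbance)


def make_mixture_dataset(
    m: int = 148,
    seed: int = 0,
    noise_sd: float = 0.005,
    scatter: bool = True,
    specs=None,
    wavelengths=None,
):
    """Tabular sample set: (SpectrumTable, ChemistryTable, SyntheticTruth).

    Defaults state the emulated survey: 148 pellets, additive sensor noise of
    0.5% reflectance, per-sample multiplicative/additive scatter on.
    """
    rng = np.random.default_rng(seed)
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths, float)
    specs = default_component_specs() if specs is None else specs
    pure = make_component_spectra(specs, wl)
    chem = _draw_concentrations(m, rng)
    refl = _reflectance_from_concentrations(chem.to_numpy(), pure)
    slopes = offsets = None
    if scatter:
        slopes = rng.uniform(0.8, 1.2, size=m)
        offsets = rng.uniform(-0.02, 0.02, size=m)
        refl = offsets[:, None] + slopes[:, None] * refl
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)
    spectra = pd.DataFrame(refl, index=chem.index, columns=wl)
    truth = SyntheticTruth(
        concentrations=chem,
        component_centers_nm={
            name: tuple(COMPONENT_CENTERS_NM[name]) + SHARED_CENTERS_NM
            for name in COMPONENTS
        },
        pure_spectra=pure,
        wavelengths=wl,
        noise_sd=noise_sd,
        scatter=scatter,
        seed=seed,
        scatter_slopes=slopes,
        scatter_offsets=offsets,
    )
    return spectra, chem, truth


def _ellipse_mask(shape, center, semi_axes) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    (r0, c0), (ar, ac) = center, semi_axes
    return ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0


def make_synthetic_cube(
    pellets: int = 2,
    seed: int = 0,
    shape: tuple[int, int] = (60, 40 * 2),
    noise_sd: float = 0.0,
    within_pellet_sd: float = 1.5,
    specs=None,
):
    """Raw cube + white/dark references + ground truth.

    Elliptical pellets are laid out left to right on a dark conveyor.  Each
    pellet gets its own mean composition (drawn from the survey statistics)
    plus a smooth zero-mean within-pellet gradient of sd ``within_pellet_sd``
    percentage points.  Raw counts are ``dark + R * (white - dark)`` rounded
    to integers in 0..4095; at the 1196 nm threshold band, background counts
    stay below 800 and pellet counts above it.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    wl = default_wavelengths()
    specs = default_component_specs() if specs is None else specs
    pure = make_component_spectra(specs, wl)

    slot = cols // pellets
    semi_r = int(rows * 0.3)
    semi_c = int(slot * 0.35)
    if semi_r < 2 or semi_c < 2:
        raise ValueError(f"image shape {shape} too small for {pellets} pellets")
    labels = np.zeros(shape, dtype=int)
    for p in range(pellets):
        center = (rows // 2, slot * p + slot // 2)
        foot = _ellipse_mask(shape, center, (semi_r, semi_c))
        if (labels[foot] != 0).any():
            raise ValueError("pellet footprints overlap; enlarge the image")
        labels[foot] = p + 1
    mask = labels > 0

    pellet_chem = _draw_concentrations(pellets, rng)
    pellet_chem.index = [f"P{i + 1}" for i in range(pellets)]

    fields = {name: np.full(shape, np.nan) for name in COMPONENTS}
    rr, cc = np.mgrid[:rows, :cols]
    for p in range(1, pellets + 1):
        foot = labels == p
        for name in COMPONENTS:
            base = float(pellet_chem.iloc[p - 1][name])
            if within_pellet_sd > 0:
                direction = rng.normal(size=2)
                direction /= np.linalg.norm(direction)
                grad = direction[0] * rr[foot] + direction[1] * cc[foot]
                grad = grad - grad.mean()
                sd = grad.std()
                grad = grad / sd * within_pellet_sd if sd > 0 else grad
            else:
                grad = 0.0
            fields[name][foot] = base + grad

    conc_pixels = np.stack(
        [np.where(mask, fields[name], 0.0) for name in COMPONENTS], axis=-1
    )
    refl = np.full((rows, cols, len(wl)), BACKGROUND_REFL)
    refl[mask] = _reflectance_from_concentrations(conc_pixels[mask], pure)
    if noise_sd > 0:
        refl = refl + rng.normal(0.0, noise_sd, size=refl.shape)

    white_line = np.full((cols, len(wl)), WHITE_COUNTS)
    dark_line = np.full((cols, len(wl)), DARK_COUNTS)
    counts = dark_line[np.newaxis] + refl * (white_line - dark_line)[np.newaxis]
    counts = np.clip(np.rint(counts), 0, SENSOR_MAX).astype(np.uint16)
    cube = SpectralCube(counts, wl, kind="raw")

    band_1196 = cube.band_index(1196.0)
    fg = counts[..., band_1196][mask]
    bg = counts[..., band_1196][~mask]
    if noise_sd == 0 and (fg.min() <= 800 or bg.max() >= 800):
        raise RuntimeError(
            "synthetic cube violates the 800-count threshold contract at 1196 nm"
        )

    pellet_means = pd.DataFrame(
        {
            name: [float(np.mean(fields[name][labels == p])) for p in range(1, pellets + 1)]
            for name in COMPONENTS
        },
        index=pellet_chem.index,
    )
    truth = SyntheticTruth(
        concentrations=pellet_chem,
        component_centers_nm={
            name: tuple(COMPONENT_CENTERS_NM[name]) + SHARED_CENTERS_NM
            for name in COMPONENTS
        },
        pure_spectra=pure,
        wavelengths=wl,
        noise_sd=noise_sd,
        scatter=False,
        seed=seed,
        mask=mask,
        labels=labels,
        concentration_fields=fields,
        pellet_means=pellet_means,
    )
    white = ReferenceFrame(white_line, "white")
    dark = ReferenceFrame(dark_line, "dark")
    return cube, white, dark, truth
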