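# Methods

## Measurement model

A push-broom NIR hyperspectral camera records a cube `I_raw[row, col, band]`
of 12-bit counts (full scale 4095) over 256 contiguous bands spanning
874.41–1733.91 nm. Reflectance is recovered per pixel and band as

    R = (I_raw − I_dark) / (I_white − I_dark)

with a dark frame (shutter closed) and a white frame (~99% reflectance
standard). Two reference conventions exist for line-scan geometry: per-pixel
references (default) and references averaged along the scan axis
(`average_references=True`), which suppresses reference noise at the cost of
ignoring per-line drift. Calibrated reflectance is deliberately **not**
clipped to [0, 1]; clipping would bias the SNV/MSC scatter statistics
computed later. Pixels where `I_white == I_dark` are flagged invalid and
excluded downstream rather than silently becoming infinite.

The spectral ends (below 958 nm and above 1683 nm) carry instrument and
illumination artifacts and are trimmed before any chemometrics; on the even
256-band grid this leaves 215 bands. (Real instruments with non-uniform
band centers can leave slightly different counts — e.g. 216 — which is why
band counts are always computed, never assumed.)

## Segmentation

Pellets sit bright on a dark conveyor at 1196 nm, so a single threshold at
800/4095 ≈ 0.195 of full scale separates foreground from background (raw
cubes are normalized by 4095 first; calibrated cubes are compared directly
— both paths are exposed because the 0.19 convention is ambiguous between
them). The rule is *strictly greater than*. "Nearest band to 1196 nm"
resolves wavelength-to-band mapping, ties toward the lower index. No
morphological cleanup is applied by default (plain thresholding is the
reference behaviour); an optional minimum-component-size filter exists for
noisy cubes. Multi-pellet images are labeled by 8-connected components.
The sample spectrum is the arithmetic mean over the ROI pixels per band.

## Pre-processing

Four pre-treatments, composable into ordered chains whose fitted statistics
come from calibration rows only:

- **MC** — subtract per-band calibration means.
- **SNV** — per spectrum `(x − mean) / sd` with the n−1 denominator;
  removes per-spectrum additive offset and multiplicative scatter exactly
  (`snv(a + b·x) = snv(x)` for `b > 0`). Errors on constant spectra.
- **MSC** — per spectrum, least-squares fit `x ≈ a + b·ref` and correct to
  `(x − a)/b`; the reference is the calibration-set mean spectrum (common
  convention; configurable). Slopes with `|b| < 1e−12` are an error.
- **2nd derivative** — Savitzky–Golay, window 11 points, polynomial order 2
  (the derivative parameters are not standardized in the field, so both are
  config keys). The derivative is taken with respect to band *index*, since
  the band grid is near-uniform; edge handling is polynomial interpolation
  (`mode="interp"`) so output length equals input length and wavelength
  bookkeeping stays aligned for SPA.

Models additionally center X and y internally, independent of an MC chain
step; MC therefore only matters when its effect differs from the model's
own centering (it does for SNV/MSC/derivative chains placed after it).

## SPXY partitioning

Joint distance `d_xy(p,q) = d_x(p,q)/max d_x + d_y(p,q)/max d_y` with
Euclidean `d_x` on spectra and Euclidean `d_y` on the z-score-standardized
response block (standardization is the default so the three components
contribute comparably; raw-y is a config option). Kennard–Stone on `d_xy`:
seed with the most distant pair, then repeatedly add the sample maximizing
the minimum joint distance to the selected set. Calibration count is
`round(m × fraction)` (148 × 0.75 = 111). One joint split serves all three
components. Ties break toward the lowest sample index, making the procedure
fully deterministic. If one block is degenerate (all-identical) its term is
dropped with a warning; both degenerate is an error.

## SPA wavelength selection

Chains are grown on column-centered calibration spectra: starting from a
band, every unselected band is projected onto the orthogonal complement of
the span of the selected ones and the band with the largest projected norm
is appended (implemented as iterative deflation, which is algebraically the
same projection). Chains truncate with a warning when all remaining
projected norms fall below 1e−10.

Selection is exhaustive over start bands and subset sizes 5–50: each
(start, size) prefix is scored by the validation RMSE of an ordinary MLR
fitted on the calibration block; minimum wins, ties prefer smaller size,
then lower start index. The validation set is an internal SPXY 3:1
sub-split of the calibration set, so the prediction set never leaks into
selection; an explicit validation set can be supplied instead. SPA runs on
spectra pre-processed with the same chain as the downstream model. No
backward-elimination phase is applied (off by default, as in the plain
formulation). Retained fractions are reported as `100 × size / n_bands` to
two decimals.

CARS is provided as an alternative: 50 Monte-Carlo runs, each subsampling
80% of calibration rows, fitting PLS, ranking bands by |coefficient|,
shrinking by an exponentially decreasing retention ratio plus adaptive
reweighted sampling, and scoring the subset by 10-fold CV RMSE; the
best-scoring subset across runs wins. Fully seeded, hence reproducible.

## Calibration models

- **PLS1** — NIPALS with deflation of X and y; single response per model
  (the three components are fitted independently). Latent-variable count =
  argmin of leave-one-out CV RMSE over 1..20, ties toward fewer LVs.
- **PC-MLR** — SVD of column-centered X; OLS of y on the leading k score
  columns (scores are orthogonal, so the coefficient path over k is
  incremental). Choosing k by "calibration performance" alone is ill-posed
  (RMSEC decreases monotonically in k), so the default reading is LOO-CV
  RMSE on the calibration set; a raw-RMSEC mode with a 1% relative
  minimum-improvement stop exists for comparison.

Both agree with the ordinary least-squares solution when the component
count equals the rank of X (asserted against the normal-equations oracle at
1e−8), and the in-repo NIPALS is cross-checked against scikit-learn's
`PLSRegression`. Reports carry `R² = 1 − SS_res/SS_tot` about the evaluated
set's own mean (canonical), plus the squared-Pearson variant some
commercial packages print; RMSE in concentration %.

A fitted `CalibrationModel` bundles the pre-processing chain (with its
statistics), the selected band indices, and the regression vector into one
JSON file; prediction aligns input bands to training wavelengths within
0.5 nm.

## Chemical maps

Every foreground pixel's spectrum goes through chain → band subset → linear
model; background stays NaN. Pixels whose chain fails (e.g. constant
spectrum under SNV) are counted and left undefined rather than aborting the
map. The median filter (3×3 default) is mask-aware: each median is taken
over the kernel neighborhood intersected with the pellet mask, so
background never bleeds into pellet edges and the filter output is bounded
by the neighborhood's own min/max. Per-pellet summaries are means over
8-connected components after filtering. Rendering uses a blue→red scale,
one scale per component, limits defaulting to the map's own range
(configurable to the calibration y-range for cross-image comparability);
the limits are written to a JSON side-car. Note that map means equal the
tabular prediction of the ROI mean spectrum only for linear chains; SNV,
MSC and derivatives break that identity, so it is asserted only for the
identity chain.

## Synthetic world

The generator states one concrete world and keeps it fixed:

- **Grid**: 256 bands, 874.41–1733.91 nm (spacing ≈ 3.37 nm); trimming
  leaves 215 bands.
- **Pure spectra**: sums of Gaussian bands (sd 10 nm ≈ 24 nm FWHM, at the
  narrow end of real NIR overtone bands) at the standard band assignments —
  cellulose 985, 1204, 1440, 1483, 1514, 1582, 1656 (the 1653/1659 vinyl
  pair merged, sub-band-spacing apart), 1683 nm; hemicellulose 1109, 1197,
  1416, 1429, 1622 nm; lignin 1264, 1534, 1646 nm; plus shared C–H/O–H
  bands at 1321, 1372, 1548, 1673 nm in all three. Own-band amplitude 0.6
  absorbance at 100% concentration, shared bands 0.35.
- **Mixing**: Beer–Lambert-style, `A = 0.25 + Σ (cᵢ/100)·pureᵢ`,
  `R = 10^−A` — so a linear model on absorbance is exactly correct and
  clean data admit machine-precision recovery by least squares (the
  tested oracle).
- **Concentrations**: truncated normals with means/sds/ranges matching a
  realistic pellet survey — cellulose 49.14 ± 7.72% in [18.94, 64.56],
  hemicellulose 18.42 ± 3.76% in [11.12, 30.98], lignin 20.25 ± 3.57% in
  [13.87, 29.12]; rows whose components would sum past 99% are redrawn.
- **Distortions**: per-sample scatter `a + b·R` with `b ~ U[0.8, 1.2]` and
  `a ~ U[−0.02, 0.02]`, plus additive Gaussian noise (default sd 0.005
  reflectance). These are exactly the distortions SNV/MSC are built to
  remove.
- **Cubes**: elliptical pellets on a conveyor of flat reflectance 0.05;
  white ≈ 3900 counts, dark ≈ 60; `counts = dark + R·(white − dark)`
  rounded into 0..4095, so calibration inverts the generator to within one
  count, background stays below the 800-count threshold at 1196 nm and
  pellets above it. Within-pellet composition varies as a smooth zero-mean
  gradient (sd 1.5 percentage points).

Everything is a pure function of (config, seed).

**What the synthetic world does not emulate**: instrument point-spread and
spectral smile, stray light, wavelength miscalibration, moisture and
temperature effects, non-Gaussian band shapes, particle-size-dependent
scattering beyond the affine model, and real covariance between components.
A green synthetic test therefore establishes algorithmic correctness and
end-to-end consistency, not instrument-grade predictive accuracy.

## Observed performance and a known limitation

At the default operating point (m = 148, noise 0.005, scatter on) the SPA
pipelines reach prediction R² ≈ 0.84–0.95 depending on component and seed —
the same tier the method achieves on real pellets. The cap is structural:
the "raw" chains used for cellulose and lignin leave the multiplicative
scatter uncorrected, and a linear model can cancel it only to first order,
so even a full-band PC-MLR tops out near R²p ≈ 0.93–0.95 here. Relatedly,
SPA's goal of minimal collinearity means it deliberately *skips* redundant
neighbours of broad overlapping bands, so it does not place a selection
near every generating band center; coverage improves with subset size but
is not guaranteed. Both behaviours are properties of the methods, not
implementation artifacts, and the test suite documents them.

## Numerical choices

- SPA rank-exhaustion threshold 1e−10 on projected norms; MSC slope
  tolerance 1e−12; PLS deflation stops when `‖X'y‖ < 1e−12`.
- PCA rank cut at `s > s_max · 1e−12`.
- All argmin/argmax tie-breaks take the first (lowest) index, making every
  stage deterministic given its inputs.
- LOO-CV curves are retained on the fitted estimators (`cv_rmse_`) so the
  choice of component count is auditable.
- Wavelength alignment tolerance for model transfer: 0.5 nm.
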