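# pelletchem

Near-infrared hyperspectral imaging chemometrics for biofuel pellets:
nondestructive prediction of **cellulose, hemicellulose and lignin**
(% dry weight) from push-broom NIR cubes, and pixel-level distribution maps
of those components across each pellet.

The package is aimed at people building NIR calibration pipelines for
densified biomass (pellet producers, biomass conversion labs): it turns raw
12-bit hyperspectral cubes plus wet-chemistry reference values into fitted
calibration models and per-pixel concentration maps, and ships a synthetic
data generator with known ground truth so the whole chain is testable
without an instrument.

## The method

1. **Reflectance calibration.** Raw counts are corrected with white/dark
   reference frames: `R = (I_raw − I_dark) / (I_white − I_dark)`.
2. **Segmentation.** Pellets are separated from the dark conveyor by
   thresholding the band nearest 1196 nm at 800/4095 of full scale; the mean
   spectrum over the pellet ROI becomes the sample spectrum. The noisy
   spectral ends are trimmed to 958–1683 nm.
3. **Pre-processing.** Mean centering (MC), standard normal variate (SNV),
   Savitzky–Golay second derivative, and multiplicative scatter correction
   (MSC), composable into chains whose statistics are learned on the
   calibration set only.
4. **SPXY partitioning.** Calibration/prediction split (3:1 by default) by
   Kennard–Stone selection on the joint metric
   `d_xy = d_x/max d_x + d_y/max d_y`.
5. **SPA wavelength selection.** The successive projections algorithm grows
   chains of minimally collinear bands from every start wavelength; subset
   size (5–50) and start are chosen by the validation RMSE of an MLR model.
   CARS (Monte-Carlo PLS-coefficient sampling with 10-fold CV) is available
   as an alternative selector.
6. **Calibration models.** PLS1 (NIPALS, latent variables by leave-one-out
   CV) and principal-component MLR (OLS on leading PCA scores, component
   count by LOO-CV), scored by R²c/R²p and RMSEC/RMSEP.
7. **Chemical maps.** The fitted model is transferred to every pellet pixel;
   a mask-aware 3×3 median filter removes salt-and-pepper noise; maps are
   rendered blue→red with per-pellet mean annotations.

Estimators follow the scikit-learn API (`fit`/`transform`/`predict`,
`get_params`), so chains and selectors compose with sklearn pipelines.

## Worked example

```sh
pelletchem all --workdir demo --samples 148 --seed 1
```

or equivalently in Python:

```python
from pelletchem.pipeline import PipelineConfig, run_training, run_mapping
from pelletchem.synthetic import make_mixture_dataset, make_synthetic_cube

spectra, chemistry, truth = make_mixture_dataset(m=148, seed=1)
result = run_training(spectra, chemistry, PipelineConfig(seed=1))
print(result["reports"])
```

prints (seed 1):

```
    component          model  Par   R2_cal    RMSEC  R2_pred    RMSEP  n_selected  retained_percent
    cellulose     SPA–PC-MLR    4 0.944820 1.631332 0.865200 1.900767           7              3.26
hemicellulose SNV–SPA–PC-MLR   20 0.978494 0.561646 0.947190 0.721186          34             15.81
       lignin     SPA–PC-MLR    9 0.955622 0.670220 0.847729 0.856481          34             15.81
```

Reading: for each component, the model name records the pre-processing
chain (SNV only helps hemicellulose), `Par` is the chosen number of
principal components, R²/RMSE are reported on the SPXY calibration and
prediction sets (RMSE in concentration %), and `retained_percent` is the
share of the 215 trimmed bands kept by SPA. Mapping the fitted models onto
a two-pellet synthetic cube then yields a per-pellet summary:

```
 label     component  mean_percent  n_pixels
     1     cellulose     49.839900       785
     2     cellulose     54.993731       785
     1 hemicellulose     14.691559       785
     2 hemicellulose     17.619691       785
     1        lignin     19.042642       785
     2        lignin     20.729179       785
```

i.e. the mean predicted concentration over each pellet's 785 pixels, to be
compared with the generator's per-pellet ground truth.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full chain from scratch at the given seed — generates the
148-sample synthetic survey, trains the three component models
(trim → SPXY → chain → SPA → PC-MLR), maps a freshly generated two-pellet
cube, prints both report tables, and writes the target JSON to `--out`.

See `docs/methods.md` for model assumptions, parameter choices, and what
the synthetic world does and does not establish.
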