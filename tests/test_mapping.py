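"""Pixel-level prediction maps, mask-aware median filtering, rendering."""

import json

import numpy as np
import pandas as pd
import pytest

from pelletchem.cube import SpectralCube, calibrate, trim_bands
from pelletchem.mapping import (
    ConcentrationMap,
    median_filter_map,
    predict_map,
    render_map,
)
from pelletchem.model import CalibrationModel
from pelletchem.preprocessing import build_chain
from pelletchem.segmentation import ForegroundMask, build_mask
from pelletchem.synthetic import make_synthetic_cube


def _identity_model(wavelengths, coef=None, component="cellulose"):
    n = len(wavelengths)
    coef = np.zeros(n) if coef is None else coef
    chain = build_chain("none").fit(np.zeros((2, n)))
    return CalibrationModel(
        component=component,
        family="pcmlr",
        chain=chain,
        wavelengths=wavelengths,
        band_indices=np.arange(n),
        n_components=1,
        coef=coef,
        intercept=0.0,
    )


@pytest.fixture(scope="module")
def constant_cube():
    """Zero-noise cube with spatially constant composition per pellet."""
    return make_synthetic_cube(pellets=2, seed=3, within_pellet_sd=0.0)


def test_constant_concentration_recovered(constant_cube, trained_default):
    cube, white, dark, truth = constant_cube
    result, _ = trained_default
    model = result["models"]["cellulose"]
    cal = trim_bands(calibrate(cube, white, dark))
    mask = build_mask(cube)
    cmap = predict_map(cal, mask, model)
    labels = truth.labels
    rmsep = result["reports"].set_index("component").loc["cellulose", "RMSEP"]
    for p in (1, 2):
        predicted = cmap.values[labels == p]
        expected = truth.pellet_means.iloc[p - 1]["cellulose"]
        assert np.all(np.isfinite(predicted))
        assert abs(np.mean(predicted) - expected) < 2 * rmsep


def test_map_matches_tabular_prediction(constant_cube, trained_default):
    # every pixel of one pellet carries the same spectrum, so the map value
    # must equal the tabular prediction of that spectrum
    cube, white, dark, truth = constant_cube
    result, _ = trained_default
    model = result["models"]["cellulose"]
    cal = trim_bands(calibrate(cube, white, dark))
    mask = build_mask(cube)
    cmap = predict_map(cal, mask, model)
    rr, cc = np.nonzero(truth.labels == 1)
    pixel = pd.DataFrame([cal.data[rr[0], cc[0]]], columns=cal.wavelengths)
    tabular = model.predict(pixel)[0]
    # quantization makes pixels differ by <= 1 count; compare loosely
    assert abs(cmap.values[rr[0], cc[0]] - tabular) < 1e-12


def test_background_only_errors():
    wl = np.linspace(874.41, 1733.91, 8)
    cube = SpectralCube(np.full((4, 4, 8), 0.01), wl, kind="calibrated")
    with pytest.raises(ValueError, match="no sample"):
        build_mask(cube)


def test_wavelength_mismatch_errors(constant_cube, trained_default):
    cube, white, dark, _ = constant_cube
    result, _ = trained_default
    model = result["models"]["cellulose"]
    cal = trim_bands(calibrate(cube, white, dark), 1100, 1500)  # too narrow
    mask = build_mask(cube)
    with pytest.raises(ValueError, match="missing"):
        predict_map(cal, mask, model)


class TestMedianFilter:
    def _map(self, values, mask):
        return ConcentrationMap(
            np.where(mask, values, np.nan),
            ForegroundMask(mask, 0.19, 1196.0),
            "cellulose",
        )

    def test_constant_map_unchanged(self):
        mask = np.ones((5, 5), bool)
        cmap = self._map(np.full((5, 5), 42.0), mask)
        out = median_filter_map(cmap)
        np.testing.assert_allclose(out.values[mask], 42.0)

    def test_single_outlier_removed(self):
        mask = np.ones((5, 5), bool)
        values = np.full((5, 5), 10.0)
        values[2, 2] = 99.0
        out = median_filter_map(self._map(values, mask))
        assert out.values[2, 2] == 10.0

    def test_mask_aware_no_background_bleed(self):
        # an edge pixel's neighborhood includes background NaNs: the median
        # must come only from in-mask values
        mask = np.zeros((3, 3), bool)
        mask[1, :] = True
        values = np.array([[0, 0, 0], [5.0, 7.0, 9.0], [0, 0, 0]])
        out = median_filter_map(self._map(values, mask))
        np.testing.assert_allclose(out.values[1], [6.0, 7.0, 8.0])
        assert np.all(np.isnan(out.values[0]))

    def test_bounds_and_double_filter_bruteforce(self, rng):
        # 9x9 binary fixture; naive loop oracle for one filtering pass
        mask = np.ones((9, 9), bool)
        values = rng.integers(0, 2, size=(9, 9)).astype(float)

        def naive(v):
            out = np.empty_like(v)
            for i in range(9):
                for j in range(9):
                    window = v[max(0, i - 1):i + 2, max(0, j - 1):j + 2]
                    out[i, j] = np.median(window)
            return out

        once = median_filter_map(self._map(values, mask))
        np.testing.assert_allclose(once.values, naive(values))
        twice = median_filter_map(once)
        changed_once = np.sum(once.values != values)
        changed_twice = np.sum(twice.values != once.values)
        assert changed_twice <= changed_once
        assert once.values.min() >= values.min()
        assert once.values.max() <= values.max()

    def test_kernel_validation(self):
        cmap = self._map(np.ones((4, 4)), np.ones((4, 4), bool))
        with pytest.raises(ValueError):
            median_filter_map(cmap, kernel=4)


class TestRender:
    def test_metadata_limits_and_colormap_ends(self, tmp_path):
        import matplotlib

        mask = np.ones((4, 4), bool)
        values = np.linspace(10, 60, 16).reshape(4, 4)
        cmap = ConcentrationMap(values, ForegroundMask(mask, 0.19, 1196.0), "lignin")
        meta = render_map(cmap, tmp_path / "map.png", vmin=15.0, vmax=55.0)
        assert (tmp_path / "map.png").exists()
        written = json.loads((tmp_path / "map.png.json").read_text())
        assert written == {"component": "lignin", "vmin": 15.0, "vmax": 55.0}
        jet = matplotlib.colormaps["jet"]
        r0, g0, b0, _ = jet(0.0)
        r1, g1, b1, _ = jet(1.0)
        assert b0 > r0 and r1 > b1  # blue end -> red end


def test_model_json_round_trip(trained_default, tmp_path, rng):
    result, _ = trained_default
    model = result["models"]["hemicellulose"]
    path = tmp_path / "model.json"
    model.save(path)
    back = CalibrationModel.load(path)
    X = pd.DataFrame(
        rng.uniform(0.1, 0.7, size=(4, len(model.wavelengths))),
        columns=model.wavelengths,
    )
    np.testing.assert_allclose(back.predict(X), model.predict(X), atol=1e-12)
    assert back.name == model.name
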