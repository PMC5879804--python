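"""End-to-end orchestration: configuration, training, and map production.

The training sequence mirrors the measurement workflow: reflectance
calibration -> pellet segmentation -> ROI extraction -> band trimming ->
SPXY split -> per component (pre-processing chain -> SPA wavelength
selection -> PLSR / PC-MLR fit -> R2/RMSE report).  ``run_mapping``
transfers the fitted models onto a cube pixel by pixel.

All stages are pure functions of their inputs plus the config seed; a
reproducibility manifest (config hash, seed, package versions) is written
next to every set of outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cube import DEFAULT_TRIM_NM, SpectralCube, calibrate, trim_bands
from .mapping import median_filter_map, predict_map, render_map
from .model import CalibrationModel
from .partition import SplitResult, spxy_split
from .preprocessing import build_chain
from .regression import PCMLRCalibration, PLSRCalibration, evaluate
from .segmentation import build_mask, mean_roi_spectrum, per_pellet_spectra
from .selection import SPAResult, cars_select, spa_select
from .synthetic import COMPONENTS

DEFAULT_CHAINS = {"cellulose": "none", "hemicellulose": "snv", "lignin": "none"}


@dataclass
class PipelineConfig:
    """Validated knobs for the whole workflow; defaults are the reference
    operating point (trim [958, 1683] nm, threshold 800/4095, 3:1 split,
    SPA sizes 5..50, PC-MLR with SNV only for hemicellulose)."""

    output_dir: str = "pelletchem_out"
    trim_lo_nm: float = DEFAULT_TRIM_NM[0]
    trim_hi_nm: float = DEFAULT_TRIM_NM[1]
    threshold: float = 800 / 4095
    threshold_band_nm: float = 1196.0
    cal_fraction: float = 0.75
    spa_n_min: int = 5
    spa_n_max: int = 50
    selector: str = "spa"  # "spa" | "cars" | "none"
    chains: dict = field(default_factory=lambda: dict(DEFAULT_CHAINS))
    families: dict = field(default_factory=lambda: {c: "pcmlr" for c in COMPONENTS})
    max_lv: int = 20
    max_pc: int = 50
    map_kernel: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cal_fraction < 1:
            raise ValueError("cal_fraction must be in (0, 1)")
        if self.trim_lo_nm >= self.trim_hi_nm:
            raise ValueError("trim_lo_nm must be < trim_hi_nm")
        if not 1 <= self.spa_n_min <= self.spa_n_max:
            raise ValueError("need 1 <= spa_n_min <= spa_n_max")
        if self.selector not in ("spa", "cars", "none"):
            raise ValueError(f"unknown selector {self.selector!r}")
        for comp, fam in self.families.items():
            if fam not in ("plsr", "pcmlr"):
                raise ValueError(f"unknown model family {fam!r} for {comp}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(asdict(self)))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def manifest(config: PipelineConfig) -> dict:
    import sklearn
    import scipy

    return {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "pelletchem": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }


# ---------------------------------------------------------------------------
# tabular training

def train_component(
    component: str,
    X_cal: pd.DataFrame,
    y_cal: np.ndarray,
    config: PipelineConfig,
) -> tuple[CalibrationModel, SPAResult | None]:
    """Chain -> wavelength selection -> model fit for one response."""
    wavelengths = np.asarray(X_cal.columns, dtype=float)
    chain = build_chain(config.chains.get(component, "none"))
    chain.fit(X_cal.to_numpy(dtype=float))
    Xp = np.asarray(chain.transform(X_cal.to_numpy(dtype=float)), dtype=float)

    spa_result = None
    if config.selector == "spa":
        sub = spxy_split(Xp, y_cal, cal_fraction=0.75)
        tr = np.asarray(sub.calibration_ids, dtype=int)
        va = np.asarray(sub.prediction_ids, dtype=int)
        spa_result = spa_select(
            Xp[tr],
            y_cal[tr],
            Xp[va],
            y_cal[va],
            n_min=config.spa_n_min,
            n_max=config.spa_n_max,
            wavelengths=wavelengths,
        )
        band_indices = spa_result.selected_indices
    elif config.selector == "cars":
        band_indices = cars_select(Xp, y_cal, seed=config.seed)
    else:
        band_indices = np.arange(Xp.shape[1])

    family = config.families.get(component, "pcmlr")
    if family == "plsr":
        reg = PLSRCalibration(max_lv=config.max_lv)
    else:
        reg = PCMLRCalibration(max_pc=config.max_pc)
    reg.fit(Xp[:, band_indices], y_cal)
    model = CalibrationModel(
        component=component,
        family=family,
        chain=chain,
        wavelengths=wavelengths,
        band_indices=band_indices,
        n_components=reg.n_components_,
        coef=reg.coef_,
        intercept=reg.intercept_,
        fitted_values=reg.fitted_values_,
    )
    return model, spa_result


def run_training(
    spectra: pd.DataFrame,
    chemistry: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Full tabular stage. Returns models, reports, split and SPA results."""
    if not spectra.index.equals(chemistry.index):
        chemistry = chemistry.loc[spectra.index]
    X = trim_bands(spectra, config.trim_lo_nm, config.trim_hi_nm)
    split = spxy_split(X, chemistry, cal_fraction=config.cal_fraction)
    X_cal, X_pred = X.loc[split.calibration_ids], X.loc[split.prediction_ids]

    models: dict[str, CalibrationModel] = {}
    spa_results: dict[str, SPAResult | None] = {}
    rows = []
    for component in chemistry.columns:
        y_cal = chemistry.loc[split.calibration_ids, component].to_numpy(dtype=float)
        y_pred = chemistry.loc[split.prediction_ids, component].to_numpy(dtype=float)
        model, spa_result = train_component(component, X_cal, y_cal, config)
        report = evaluate(model, X_cal, y_cal, X_pred, y_pred)
        models[component] = model
        spa_results[component] = spa_result
        row = {"component": component, "model": model.name, **report.to_row()}
        if spa_result is not None:
            row["n_selected"] = spa_result.chosen_size
            row["retained_percent"] = spa_result.retained_fraction(X.shape[1])
        rows.append(row)
    return {
        "models": models,
        "reports": pd.DataFrame(rows),
        "split": split,
        "spa": spa_results,
        "trimmed_wavelengths": np.asarray(X.columns, dtype=float),
    }


def save_training_outputs(result: dict, config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    for component, model in result["models"].items():
        model.save(out / "models" / f"{component}.json")
    result["reports"].to_csv(out / "report.csv", index=False)
    result["split"].save(out / "split.csv")
    for component, spa_result in result["spa"].items():
        if spa_result is None:
            continue
        spa_result.report().to_csv(out / f"spa_{component}.csv", index=False)
        pd.DataFrame(
            {
                "size": list(spa_result.rmsev_by_size),
                "rmsev": list(spa_result.rmsev_by_size.values()),
            }
        ).to_csv(out / f"spa_{component}_curve.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(manifest(config), indent=1))
    return out


# ---------------------------------------------------------------------------
# imaging

def extract_roi_table(
    cube: SpectralCube, config: PipelineConfig, per_pellet: bool = False
) -> pd.DataFrame:
    """Calibrated cube -> ROI mean spectra table (whole mask or per pellet)."""
    mask = build_mask(cube, config.threshold_band_nm, config.threshold)
    if per_pellet:
        return per_pellet_spectra(cube, mask)
    spectrum = mean_roi_spectrum(cube, mask)
    return pd.DataFrame([spectrum], index=["roi"], columns=cube.wavelengths)


def run_mapping(
    cube: SpectralCube,
    white,
    dark,
    models: dict[str, CalibrationModel],
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    render: bool = True,
) -> dict:
    """Calibrate -> mask -> per-component pixel maps -> summaries."""
    calibrated = calibrate(cube, white, dark) if cube.kind == "raw" else cube
    mask = build_mask(calibrated if cube.kind != "raw" else cube,
                      config.threshold_band_nm, config.threshold)
    trimmed = trim_bands(calibrated, config.trim_lo_nm, config.trim_hi_nm)
    maps = {}
    summaries = []
    for component, model in models.items():
        cmap = predict_map(trimmed, mask, model)
        cmap = median_filter_map(cmap, kernel=config.map_kernel)
        maps[component] = cmap
        summaries.append(cmap.summarize())
    summary = pd.concat(summaries, ignore_index=True)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "per_pellet_summary.csv", index=False)
        if render:
            for component, cmap in maps.items():
                render_map(cmap, out / f"map_{component}.png", annotate=True)
        (out / "manifest.json").write_text(json.dumps(manifest(config), indent=1))
    return {"maps": maps, "summary": summary, "mask": mask}
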