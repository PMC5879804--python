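import numpy as np
import pytest

from pelletchem.pipeline import PipelineConfig, run_training
from pelletchem.synthetic import make_mixture_dataset, make_synthetic_cube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mixture_default():
    """The reference synthetic survey: 148 pellets, 0.5% noise, scatter on."""
    return make_mixture_dataset(m=148, seed=0)


@pytest.fixture(scope="session")
def trained_default(mixture_default):
    """Full training run (trim, SPXY, SPA, PC-MLR) on the reference survey."""
    spectra, chem, truth = mixture_default
    result = run_training(spectra, chem, PipelineConfig(seed=0))
    return result, truth


@pytest.fixture(scope="session")
def synthetic_cube():
    """Two-pellet raw cube with references and ground truth, zero noise."""
    return make_synthetic_cube(pellets=2, seed=0)


@pytest.fixture
def small_mixture():
    """Clean 30-sample set (no scatter, no noise) for exact-recovery tests."""
    return make_mixture_dataset(m=30, seed=7, noise_sd=0.0, scatter=False)
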