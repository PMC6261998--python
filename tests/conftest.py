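import numpy as np
import pytest

from magspim import ExperimentConfig, OpticsModel, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_phantom():
    return make_phantom(100.0, 40, 60.0, seed=11)


@pytest.fixture
def clean_optics():
    """No noise, no depth-dependent degradation."""
    return OpticsModel(
        attenuation_length=np.inf,
        blur_sigma0=3.0,
        blur_growth=0.0,
        background_mean=50.0,
        background_sd=0.0,
    )


@pytest.fixture
def degraded_optics():
    return OpticsModel(
        attenuation_length=120.0,
        blur_sigma0=2.0,
        blur_growth=0.05,
        background_mean=50.0,
        background_sd=0.0,
    )


@pytest.fixture
def default_config():
    return ExperimentConfig()
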