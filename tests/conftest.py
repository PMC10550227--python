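import numpy as np
import pytest

from anisopipe import (
    ImagingParams,
    KineticsParams,
    OpticsConfig,
    PolarizedFrame,
    PreprocessConfig,
    SensorParams,
    make_phantom,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_optics():
    """Objective/detection state matching the simulated instrument."""
    return OpticsConfig(g_factor=1.25, numerical_aperture=1.3, refractive_index=1.518)


@pytest.fixture
def no_background():
    return PreprocessConfig(background=0.0, lower_fraction=0.0, upper_fraction=0.0)


@pytest.fixture
def small_phantom():
    return make_phantom((48, 48), n_cells=20, seed=3)


@pytest.fixture
def sensor():
    return SensorParams()


@pytest.fixture
def kinetics():
    return KineticsParams()


@pytest.fixture
def noiseless_imaging():
    return ImagingParams(poisson_noise=False, scatter_alpha_per_um=0.0)


def uniform_frame(par_value, perp_value, shape=(8, 8), **meta):
    return PolarizedFrame(
        np.full(shape, float(par_value)), np.full(shape, float(perp_value)), **meta
    )
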