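import numpy as np
import pytest

from gradpredict.core import GradientWaveform, Library
from gradpredict.simulator import GradientSystemModel, simulate_library
from gradpredict.waveforms import LibraryConfig, build_characterization_library

DT = 8e-6  # coarse raster keeps the suite fast; content is < 15 kHz


@pytest.fixture(scope="session")
def lib_z() -> Library:
    """Default 18-shape nominal library on the z axis."""
    return build_characterization_library(LibraryConfig(axes=("z",), dt=DT))


@pytest.fixture(scope="session")
def paired_z(lib_z) -> Library:
    """z-axis library measured through the default nonlinear simulator."""
    return simulate_library(GradientSystemModel(rng_seed=7), lib_z, seed=7)


@pytest.fixture(scope="session")
def paired_z_lti(lib_z) -> Library:
    """z-axis library measured through the exactly-LTI simulator (noiseless)."""
    model = GradientSystemModel().lti_limit()
    return simulate_library(model, lib_z, add_noise=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_test_wave(samples, dt=DT, axis="z", **kw) -> GradientWaveform:
    return GradientWaveform(np.asarray(samples, dtype=float), dt, axis=axis, **kw)
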