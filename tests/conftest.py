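import numpy as np
import pytest

from specmap.hsio import HSCube, SpectralAxis
from specmap.response import TargetSystemSpec
from specmap.synthdata import build_target_response, default_source_system


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def target_spec():
    return TargetSystemSpec()


@pytest.fixture(scope="session")
def sr_medium():
    """Medium-mode normalized response matrix on the default dense grid."""
    return build_target_response(mode="medium")


@pytest.fixture(scope="session")
def source_full():
    return default_source_system("full")


@pytest.fixture(scope="session")
def source_selected():
    return default_source_system("selected")


def make_cube(values, wavelengths=None, state="raw"):
    values = np.asarray(values, dtype=float)
    if wavelengths is None:
        wavelengths = 500.0 + 5.0 * np.arange(values.shape[2])
    return HSCube(values=values, axis=SpectralAxis(np.asarray(wavelengths, float)), state=state)


@pytest.fixture
def random_cube(rng):
    return make_cube(rng.uniform(0.1, 1.0, (4, 5, 8)))
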