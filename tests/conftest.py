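import numpy as np
import pytest

from wfpi import simulate as sim
from wfpi.types import IntensityImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale bench: 128 grid, 7 mm pupil, reference plane separation."""
    return sim.SimulationConfig(grid_size=128)


@pytest.fixture(scope="session")
def defocus_pair(small_config):
    """Intensity pair for a +1 D artificial eye, with its ground truth."""
    truth = sim.phase_from_refraction(1.0, 0.0, 0.0, small_config)
    i1, i2 = sim.simulate_pair(truth, small_config)
    return i1, i2, truth


def uniform_image(n=32, value=1.0):
    return IntensityImage(values=np.full((n, n), value))
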