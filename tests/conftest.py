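import numpy as np
import pytest

from gcwater.energy import EnergyParams
from gcwater.model import SimulationRegion, WaterModel


@pytest.fixture(scope="session")
def params():
    return EnergyParams()


@pytest.fixture(scope="session")
def tip4p():
    return WaterModel.tip4p()


@pytest.fixture(scope="session")
def ideal_model():
    """A single-site, chargeless, LJ-free 'water': an ideal-gas particle."""
    return WaterModel(
        site_offsets=[[0.0, 0.0, 0.0]],
        site_charges=[0.0],
        oxygen_lj_sigma=0.0,
        oxygen_lj_epsilon=0.0,
        name="ideal",
    )


@pytest.fixture
def small_region():
    return SimulationRegion([-1.0, -1.0, -1.0], [1.0, 1.0, 1.0], droplet_radius=10.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
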