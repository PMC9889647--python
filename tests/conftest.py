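import numpy as np
import pytest

from leafseq.core import Grid3, MachineModel
from leafseq import simulation


@pytest.fixture(scope="session")
def machine():
    return MachineModel()


@pytest.fixture(scope="session")
def small_grid():
    """A 32^3, 6 mm grid centred on the origin — fast but large enough
    for rotations and projections to be meaningful."""
    half = 31 * 6.0 / 2.0
    return Grid3((32, 32, 32), (6.0, 6.0, 6.0), (-half, -half, -half))


@pytest.fixture(scope="session")
def phantom(small_grid):
    return simulation.sample_phantom(11, small_grid)


@pytest.fixture(scope="session")
def plan(machine, phantom):
    return simulation.sample_plan(13, machine, phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
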