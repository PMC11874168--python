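import numpy as np
import pytest

from funqee.synthetic_data import SimulationTruth, TimeGrid, simulate_study


@pytest.fixture(scope="session")
def grid30() -> TimeGrid:
    return TimeGrid.hourly(30)


@pytest.fixture(scope="session")
def default_study():
    """The default 256-subject study, shared across tests."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def small_study():
    """A small, fast study for pipeline plumbing tests."""
    return simulate_study(SimulationTruth(n=60, n_schools=3, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
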