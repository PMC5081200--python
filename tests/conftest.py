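import numpy as np
import pytest
from hypothesis import settings

from delayrc.dde import MGParams
from delayrc.model import PhaseSchedule, ReservoirConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return MGParams()


@pytest.fixture(scope="session")
def small_reservoir():
    """Desk-size reservoir for unit tests: 30 nodes on a 60-point delay."""
    return ReservoirConfig(n=30, tau=60.0, grid=60)


@pytest.fixture(scope="session")
def tiny_schedule():
    """Just enough steps to exercise every phase boundary."""
    return PhaseSchedule(offset=10, teacher_forcing=300, training=200, validation=200)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
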