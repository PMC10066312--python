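import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sacmem import default_config
from sacmem.protocol import ProtocolSchedule, familiarize


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def schedule():
    return ProtocolSchedule()


@pytest.fixture(scope="session")
def network(cfg, schedule):
    return familiarize(schedule, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
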