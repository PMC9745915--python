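import numpy as np
import pytest
from hypothesis import settings

from dlnq import PercentileSpec, rainfall_fixture, summarize

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rain_groups():
    return rainfall_fixture()


@pytest.fixture(scope="session")
def rain_summaries(rain_groups):
    return [summarize(g) for g in rain_groups]


@pytest.fixture(scope="session")
def spec95():
    return PercentileSpec(p=0.95, alpha=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
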