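import pytest
from hypothesis import settings

from ppgwas.mpc import Engine, RingConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def small_engine():
    """Engine on a tiny ring (k=8) for exhaustive protocol checks."""
    return Engine(RingConfig(8), seed=1234)


@pytest.fixture
def engine():
    """Default 128-bit engine."""
    return Engine(RingConfig(128), seed=1234)


@pytest.fixture
def engine_factory():
    def make(k=128, seed=1234, capacity=None):
        return Engine(RingConfig(k), seed=seed, triple_capacity=capacity)

    return make
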