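import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fetalwave.signal import Signal
from fetalwave.synth import generate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230844)


@pytest.fixture(scope="session")
def dyadic_signal(rng):
    """Random dyadic-length signal for exactness checks."""
    return Signal(rng.normal(size=256), fs=256.0)


@pytest.fixture(scope="session")
def default_record():
    """The reference synthetic abdominal record (seed 7)."""
    return generate(seed=7)


@pytest.fixture(scope="session")
def maternal_only_record():
    """Maternal-only variant of the reference record."""
    return generate(seed=7, amplitude_ratio=0.0)
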