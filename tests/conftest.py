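import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gsrtrng.signal_io import ByteStream

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def uniform_mb():
    """1 MiB of seeded uniform bytes, shared across statistical tests."""
    rng = np.random.default_rng(123)
    return ByteStream(rng.integers(0, 256, 2**20, dtype=np.uint8))


@pytest.fixture(scope="session")
def fair_bits_1m():
    """10^6 seeded fair bits."""
    rng = np.random.default_rng(321)
    return rng.integers(0, 2, 10**6, dtype=np.uint8)
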