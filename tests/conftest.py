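import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from softshock.constitutive import ACConfig, gelatin_tripathi

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gelatin():
    """Full three-mechanism gelatin preset."""
    return gelatin_tripathi()


@pytest.fixture(scope="session")
def gelatin_elastic():
    return gelatin_tripathi(elastic=True)


@pytest.fixture(scope="session")
def gelatin_linear():
    """Linearised elastic branch used by the small-strain studies."""
    return gelatin_tripathi(linear=True, elastic=True)


@pytest.fixture(scope="session")
def ac09():
    return ACConfig(epsilon=0.9)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
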