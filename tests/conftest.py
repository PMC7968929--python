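import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grncontext import ModelParameters, enumerate_arrangements, parse_label

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fitted_params() -> ModelParameters:
    """An admissible parameter point of the six-strain fit."""
    return ModelParameters(K=0.1, mu=0.6, tau=0.4)


@pytest.fixture(scope="session")
def null_params() -> ModelParameters:
    """Topology-only parameters: no read-through."""
    return ModelParameters(K=0.1, mu=0.0, tau=0.4)


@pytest.fixture(scope="session")
def all48():
    return enumerate_arrangements()


@pytest.fixture(scope="session")
def six_forward():
    return enumerate_arrangements(allow_reverse=False)


@pytest.fixture
def tlc():
    return parse_label("TLC")


@pytest.fixture
def clt():
    return parse_label("CLT")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
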