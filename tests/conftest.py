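from hypothesis import HealthCheck, settings
import pytest

from yfrag.align import ScoringScheme
from yfrag.resources import hy_reference_records
from yfrag.synthetic import default_reference_set

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scoring():
    return ScoringScheme()


@pytest.fixture(scope="session")
def hy_refs():
    return hy_reference_records()


@pytest.fixture(scope="session")
def refset():
    """hY genes plus random references for the other classes."""
    return default_reference_set(seed=1)
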