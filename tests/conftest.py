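import pytest
from hypothesis import HealthCheck, settings

from rulegen import canonical_distribution

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def skew4():
    return canonical_distribution("Skew4")


@pytest.fixture
def unif4():
    return canonical_distribution("Unif4")


@pytest.fixture
def unif8():
    return canonical_distribution("Unif8")
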