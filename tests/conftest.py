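import pytest
from hypothesis import HealthCheck, settings

from aavprocess.synth import gen_reference_scenario

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scenario():
    """The shipped three-platform reference scenario."""
    return gen_reference_scenario()


@pytest.fixture(scope="session")
def quantum(scenario):
    return scenario.platform("Quantum")


@pytest.fixture(scope="session")
def facility(scenario):
    return scenario.facility
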