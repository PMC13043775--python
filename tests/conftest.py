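import pytest
from hypothesis import HealthCheck, settings

from gemscout import make_chain3, make_toy_network

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def chain3():
    return make_chain3()


@pytest.fixture(scope="session")
def toy9():
    return make_toy_network()
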