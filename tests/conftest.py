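import pytest
from hypothesis import HealthCheck, settings

from dishsoup import egf_fixture, vending_fixture

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def egf_kb():
    return egf_fixture()


@pytest.fixture(scope="session")
def vending_kb():
    return vending_fixture()
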