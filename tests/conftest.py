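import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def kl25a():
    from kirchpk import kl25a_study

    return kl25a_study()


@pytest.fixture
def scheme1():
    from kirchpk import scheme1_network

    return scheme1_network()
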