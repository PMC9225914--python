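import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def standard():
    from moxitherm import standard_condition
    return standard_condition()


@pytest.fixture(scope="session")
def validation():
    from moxitherm import validation_condition
    return validation_condition()
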