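import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def designs():
    from opsintune import load_reference_designs

    return load_reference_designs()


@pytest.fixture(scope="session")
def pocket_map(designs):
    return designs.pocket_map()
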