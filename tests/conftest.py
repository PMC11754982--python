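import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from stairsafe import (
    classify_flights,
    filter_observations,
    study_flights,
    study_observations,
)


@pytest.fixture(scope="session")
def fixture_flights():
    return study_flights()


@pytest.fixture(scope="session")
def fixture_classes(fixture_flights):
    return classify_flights(fixture_flights)


@pytest.fixture(scope="session")
def fixture_observations():
    return study_observations()


@pytest.fixture(scope="session")
def fixture_retained(fixture_observations):
    kept, tally = filter_observations(fixture_observations)
    return kept, tally
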