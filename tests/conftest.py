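import pytest
from hypothesis import HealthCheck, settings

from polymito import synthetic_data as synth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def genome_bundle():
    """One default synthetic mitogenome shared across tests."""
    return synth.make_genome(seed=11)


@pytest.fixture(scope="session")
def genome(genome_bundle):
    return genome_bundle[0]


@pytest.fixture(scope="session")
def features(genome_bundle):
    return genome_bundle[1]


@pytest.fixture(scope="session")
def manifest(genome_bundle):
    return genome_bundle[2]


@pytest.fixture(scope="session")
def features_by_name(features):
    return {f.name: f for f in features}
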