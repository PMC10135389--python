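import pytest
from hypothesis import HealthCheck, settings

from ratwelfare.synthetic_cohort import default_config, simulate_cohort
from ratwelfare.welfare_scoring import default_rubric

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rubric():
    return default_rubric()


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def cohort(config):
    """One default simulated cohort, shared across tests."""
    return simulate_cohort(config, seed=20230418)


@pytest.fixture(scope="session")
def replicates_500(config):
    """500 independently seeded replicates of the default cohort."""
    return [simulate_cohort(config, seed=s) for s in range(1, 501)]
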