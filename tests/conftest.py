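import pytest
from hypothesis import HealthCheck, settings

from ceatree.synthetic_data import GeneratorConfig, generate_trial

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort():
    """The shipped fixture cohort: default study conditions, seed 0."""
    return generate_trial(GeneratorConfig(seed=0))


@pytest.fixture()
def margin_cohort():
    from helpers import exact_margin_cohort
    return exact_margin_cohort()
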