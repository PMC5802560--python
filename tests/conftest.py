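import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from gutbrain import CohortDesign, ForestConfig, generate_cohort  # noqa: E402


@pytest.fixture(scope="session")
def strong_cohort():
    """Default study-shaped cohort: 4 diets x 5 animals, strong planted signal."""
    return generate_cohort(CohortDesign(seed=7))


@pytest.fixture(scope="session")
def small_cfg():
    """Forest configuration light enough for per-test fits."""
    return ForestConfig(ntree=120, seed=3)
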