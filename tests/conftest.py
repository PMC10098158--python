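import pytest
from hypothesis import settings, HealthCheck

from lglpheno.config import GeneratorConfig
from lglpheno.synth_cohort import generate_cohort
from lglpheno.cyto_gating import extract_cohort_features

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A scaled-down cohort: enough HC donors to derive thresholds,
    few enough events that the whole suite stays fast."""
    return GeneratorConfig(
        group_sizes={"HC": 12, "LOW": 8, "HIGH": 8},
        events_per_sample=4000, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """All-panel, all-visit features for the small cohort."""
    return extract_cohort_features(small_cohort)
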