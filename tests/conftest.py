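import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from methylfunnel import (  # noqa: E402
    SimulationConfig,
    generate_beta,
    generate_cohort,
    generate_manifest,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_loci=200, n_planted=5, seed=42)


@pytest.fixture(scope="session")
def small_study(small_config):
    """A small simulated study shared across read-only tests."""
    cohort = generate_cohort(small_config)
    manifest = generate_manifest(small_config)
    beta, truth = generate_beta(cohort, manifest, small_config)
    return cohort, manifest, beta, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160107)
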