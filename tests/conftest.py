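import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nirsentropy import (
    SyntheticCohortConfig,
    generate_cohort,
    preprocess_cohort,
)
from nirsentropy.calibration import monte_carlo

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort (4v4 subjects, 6 channels) for fast unit tests."""
    return SyntheticCohortConfig(
        n_per_group=4, n_channels=6, affected_channels=(1, 3), seed=42
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_hb(small_cohort):
    recordings, _ = small_cohort
    return preprocess_cohort(recordings)


@pytest.fixture(scope="session")
def null_monte_carlo():
    """200 full-pipeline null cohorts (complexity_effect = 0, 11v11, 21
    channels), shared by the calibration checks."""
    return monte_carlo(200, effect=0.0, base_seed=20_000)
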