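import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bbspace as b

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size planted cohort (436 subjects, 718 parcels, 5 factors)."""
    return b.generate_cohort(b.CohortConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for fast structural tests."""
    return b.generate_cohort(b.CohortConfig(
        n_subjects=120, n_parcels=40, n_latent=2,
        latent_variance_fractions=(0.25, 0.15),
        coupling_strengths=(0.7, 0.7), seed=11))
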