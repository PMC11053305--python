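import numpy as np
import pytest

from fragscreen import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_config():
    """Reduced cohort: 20 bins over 4 arms, fixed enrichment, full tumor signal."""
    return sd.CohortConfig(
        seed=11,
        n_cases=12,
        n_controls=12,
        n_bins=20,
        n_arms=4,
        fragments_per_sample=20_000,
        enrichment_range=(2.0, 2.0),
        tumor_fraction=1.0,
    )


@pytest.fixture
def small_cohort(small_config):
    return sd.make_cohort(small_config)


@pytest.fixture
def small_binset(small_config):
    return sd.make_binset(small_config)
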