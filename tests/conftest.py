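import numpy as np
import pytest

from szpath import CohortSpec, generate_cohort
from szpath.synth import random_skeleton


@pytest.fixture(scope="session")
def small_skeleton():
    """Endpoint pathways: 8 windows, 4 channels, 6 bands (36 features)."""
    return random_skeleton(n_windows=8, n_channels=4, seed=11)


@pytest.fixture(scope="session")
def linear_cohort():
    """Noiseless linear-drift cohort: dissimilarity ranks follow time."""
    spec = CohortSpec(
        n_seizures=10,
        monitoring_days=7.0,
        n_channels=4,
        windows_per_seizure=(8, 14),
        drift_params=(1.0, 0.0, 0.0),
        min_gap_days=0.1,
        seed=5,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
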