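import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from zebrahab.cohort import default_profiles, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort shared across tests that only need structure."""
    return generate_cohort(
        default_profiles(),
        seed=123,
        n_per_group={"control": 6, "low_impact": 4, "high_impact": 4},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
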