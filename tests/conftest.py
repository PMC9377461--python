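import numpy as np
import pytest

from fallstay import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def midsize_cohort():
    """A 20k-subject confounded cohort shared by read-only tests."""
    return generate_cohort(CohortConfig(n_subjects=20_000, seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
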