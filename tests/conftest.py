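import numpy as np
import pytest

from facit_mcid.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One study-condition cohort (n=144), shared across tests."""
    return generate_cohort(CohortSpec(n_patients=144, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort for convergence checks on marginals/correlations."""
    return generate_cohort(CohortSpec(n_patients=10_000, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
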