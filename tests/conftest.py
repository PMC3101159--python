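import numpy as np
import pytest

from raschcat import (
    CohortSpec,
    RatingScale,
    misfit_filter,
    packaged_bank,
    simulate_cohort,
)

#: Published step calibrations of the 24-item job-satisfaction scale.
REFERENCE_TAU = (-4.16, -1.50, 2.66)


@pytest.fixture(scope="session")
def bank37():
    """The packaged 37-item bank (24 calibrated + 13 misfit rows)."""
    return packaged_bank()


@pytest.fixture(scope="session")
def bank24(bank37):
    """The 24 retained (fitting) items with the shared rating scale."""
    retained, _ = misfit_filter(bank37)
    return retained


@pytest.fixture(scope="session")
def reference_scale():
    return RatingScale(REFERENCE_TAU)


@pytest.fixture(scope="session")
def cohort300(bank24):
    """One reproducible 300-person cohort from the reference distribution."""
    thetas, matrix = simulate_cohort(CohortSpec(n_persons=300, seed=42), bank24)
    return thetas, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
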