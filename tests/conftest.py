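import numpy as np
import pytest

from gradientshift import CohortConfig, StudySpec, make_gradient_basis, simulate_cohort
from gradientshift.simulate import (HIGHER_IS_MORE_NEGATIVE,
                                    HIGHER_IS_MORE_POSITIVE)


def small_cohort_config(**overrides) -> CohortConfig:
    """A scaled-down two-study world for fast unit tests."""
    defaults = dict(
        studies=(
            StudySpec("studyA", 18, 1.0, 9.0, HIGHER_IS_MORE_NEGATIVE),
            StudySpec("studyB", 12, 1.0, 5.0, HIGHER_IS_MORE_POSITIVE),
        ),
        seed=42,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def basis400():
    return make_gradient_basis(400, K=5, seed=11)


@pytest.fixture(scope="session")
def cohort(basis400):
    return simulate_cohort(small_cohort_config(), basis400)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
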