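import pytest

from comphet.synthetic_cohort import CohortSimParams, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized cohort (149 families, 47 trios) at a fixed seed."""
    return generate_cohort(CohortSimParams(seed=7))


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-family cohort for fast I/O round-trips."""
    return generate_cohort(CohortSimParams(n_families=12, trio_fraction=0.5, seed=3))
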