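import numpy as np
import pytest

from brainarrow.synthetic import SyntheticCohortSpec, generate_cohort, toy_fixtures


@pytest.fixture
def toys():
    return toy_fixtures()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared by synthetic/pipeline tests (16 nodes, 4+4)."""
    spec = SyntheticCohortSpec(n_nodes=16, n_subjects=4, volumes=120, seed=7)
    return generate_cohort(spec)
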