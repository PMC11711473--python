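import numpy as np
import pytest

from neogenet import SyntheticCohortSpec, generate_cohort, generate_geometry


@pytest.fixture(scope="session")
def geometry30():
    """Small bilateral geometry shared across tests."""
    return generate_geometry(30, rng=np.random.default_rng(101))


@pytest.fixture(scope="session")
def geometry90():
    return generate_geometry(90, rng=np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort on 30 nodes; fast enough for construction tests."""
    spec = SyntheticCohortSpec(n_subjects=12, n_nodes=30, rng_seed=5)
    return generate_cohort(spec)


def random_adjacency(n, p, rng):
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    return a + a.T
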