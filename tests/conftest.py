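import numpy as np
import pytest

from clusterbma import SimSpec, generate_clusters


@pytest.fixture(scope="session")
def three_blobs():
    """Well-separated 3-cluster 2-D dataset (150 points) for adapter tests."""
    return generate_clusters(SimSpec(3, 50, 2, 0.6, seed=101))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def random_soft_allocation(rng, n, k):
    """Rows drawn from a Dirichlet: a valid soft allocation matrix."""
    return rng.dirichlet(np.ones(k), size=n)
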