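import numpy as np
import pytest

import cloudsig as cs


@pytest.fixture(scope="session")
def sig4():
    """Well-separated 4-signature synthetic emission matrix."""
    return cs.synthetic_signatures(4, separation=0.92, seed=7)


@pytest.fixture(scope="session")
def sig3():
    return cs.synthetic_signatures(3, separation=0.9, seed=1)


@pytest.fixture
def random_params():
    """Factory: random valid model parameters for a given signature matrix."""

    def make(signatures, rng):
        K = signatures.K
        return cs.CloudSignatureParams(
            pi=rng.dirichlet(np.ones(K)),
            A=rng.dirichlet(np.ones(K), size=K),
            rho=rng.dirichlet(np.ones(2)),
            B=rng.dirichlet(np.ones(2), size=2),
            signatures=signatures,
            threshold=2000,
        )

    return make


@pytest.fixture
def random_instance(random_params):
    """Factory: (params, partitioned sequence) with a random small layout."""

    def make(signatures, rng, max_T=8):
        T = int(rng.integers(1, max_T))
        positions = np.cumsum(rng.integers(1, 5000, size=T))
        categories = rng.integers(0, 96, size=T)
        part = cs.label_sky_cloud(positions, 2000, categories)
        return random_params(signatures, rng), part

    return make
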