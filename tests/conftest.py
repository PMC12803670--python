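import numpy as np
import pytest

from nervefa.synthetic import default_protocol


@pytest.fixture(scope="session")
def protocol():
    """3 b0 volumes + 30 directions at b = 1000 s/mm^2."""
    return default_protocol()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


def random_symmetric_tensor(rng, lam=(1.7e-3, 0.4e-3, 0.2e-3)):
    """A random rotation of a fixed eigenvalue triple."""
    from scipy.stats import special_ortho_group

    R = special_ortho_group.rvs(3, random_state=rng)
    D = R @ np.diag(lam) @ R.T
    return np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])
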