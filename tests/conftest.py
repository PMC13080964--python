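import numpy as np
import pytest

from glycancheck.reference import default_dictionary
from glycancheck.synthetic import GLYCAN_LIBRARY, build_glycan


@pytest.fixture(scope="session")
def dictionary():
    return default_dictionary()


@pytest.fixture(scope="session")
def lactose_model(dictionary):
    """Clean synthetic lactose (GAL-beta-1,4-GLC); do not mutate."""
    return build_glycan(GLYCAN_LIBRARY["lactose"], dictionary)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish proper rotation from a random matrix QR."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
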