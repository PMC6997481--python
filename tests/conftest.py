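import numpy as np
import pytest

from hingeflex import build_topology


@pytest.fixture(scope="session")
def hinge_ref():
    """Native hinge-peptide topology and idealized reference structure."""
    topo, struct = build_topology("hinge_peptide")
    return topo, struct


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rigid_transform(rng):
    """A uniformly random proper rotation and a random translation."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    r = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-3, 3, size=3)
    return r, t
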