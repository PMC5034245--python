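import numpy as np
import pytest

from helixforge.fixtures import canonical_parameters
from helixforge.model import generate_helix_coordinates


def four_point_torsion(p1, p2, p3, p4):
    """Independent IUPAC torsion oracle (praxeolitic formula), degrees."""
    b0 = p1 - p2
    b1 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    b2 = p4 - p3
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return np.degrees(np.arctan2(y, x))


def wrap_deg(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def random_rigid_transform(rng):
    """Proper rotation + translation drawn from a seeded generator."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=10.0, size=3)
    return Q, t


@pytest.fixture
def alpha_params():
    return canonical_parameters("alpha")


@pytest.fixture
def alpha_coords(alpha_params):
    return generate_helix_coordinates(alpha_params, None, np.arange(18))


@pytest.fixture
def rng():
    return np.random.default_rng(20160923)
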