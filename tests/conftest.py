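import numpy as np
import pytest
from hypothesis import settings

from cocorod import TrunkGeometry, load_preset

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def wct_params():
    """Shipped West Coast Tall preset (printed constants, synthetic anchors)."""
    return load_preset("wct")


@pytest.fixture
def wct_geometry():
    """Taper geometry calibrated to the WCT anchor radii."""
    return TrunkGeometry.from_anchors(0.16, 0.14, 1.4, rho_prime=600.0, g=9.8)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_unit_vectors(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def random_rotation_matrices(rng, n):
    """Uniform-ish random right-handed orthonormal triads (rows)."""
    from scipy.spatial.transform import Rotation
    return Rotation.random(n, random_state=np.random.RandomState(
        rng.integers(2**31))).as_matrix()
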