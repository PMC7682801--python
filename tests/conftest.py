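import numpy as np
import pytest

from cardiomorph.synthetic import ShapeParams, make_lv_mesh


@pytest.fixture(scope="session")
def canonical_params() -> ShapeParams:
    """Noise-free reference ventricle used across the geometry tests."""
    return ShapeParams(length=80.0, r_endo_base=20.0, wall_thickness=6.0)


@pytest.fixture(scope="session")
def canonical_mesh(canonical_params):
    return make_lv_mesh(canonical_params, grid=(48, 20))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rigid_transform(rng: np.random.Generator):
    """A proper rotation (via QR) and a translation, for invariance tests."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-30, 30, 3)
    return q, t
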