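import numpy as np
import pytest

from curvemark.io import LandmarkConfiguration, SurfaceMesh
from curvemark.phantoms import PhantomSpec, make_surface


@pytest.fixture
def tetra_mesh() -> SurfaceMesh:
    """Regular-ish tetrahedron: the smallest closed triangle mesh."""
    verts = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0],
                      [5.0, 8.66, 0.0], [5.0, 2.89, 8.16]])
    faces = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    return SurfaceMesh(vertices=verts, faces=faces)


@pytest.fixture
def tetra_config() -> LandmarkConfiguration:
    return LandmarkConfiguration(
        ["apex", "base1", "base2", "base3"],
        np.array([[5.0, 2.89, 8.16], [0.0, 0.0, 0.0],
                  [10.0, 0.0, 0.0], [5.0, 8.66, 0.0]]),
    )


@pytest.fixture(scope="session")
def sphere50():
    """50 mm sphere phantom shared by the curvature tests."""
    return make_surface(PhantomSpec(kind="sphere", radius=50.0, spacing=5.0))


@pytest.fixture(scope="session")
def ridge_phantom():
    """Extruded Gaussian ridge z = 5 exp(-x^2/18); crest at x = 0."""
    return make_surface(PhantomSpec(kind="gaussian-ridge", height=5.0,
                                    width=3.0, spacing=1.0, extent=15.0))


def random_rotation(seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
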