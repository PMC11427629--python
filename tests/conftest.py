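import numpy as np
import pytest

from surfbind.fixtures import make_canonical_mesh, make_toy_structure
from surfbind.mesh import SurfaceMesh, generate_surface


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def random_cloud_mesh(n: int, seed: int, box: float = 12.0) -> SurfaceMesh:
    """A random point cloud with unit normals, wrapped as a (faceless)
    SurfaceMesh for graph-layer tests."""
    rng = np.random.default_rng(seed)
    V = rng.uniform(-box, box, size=(n, 3))
    nrm = rng.normal(size=(n, 3))
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    mesh = SurfaceMesh(V, np.zeros((0, 3), dtype=int))
    mesh.normals = nrm
    return mesh


@pytest.fixture(scope="session")
def toy_structure():
    structure, na = make_toy_structure(8, seed=3, na_offset=4.0, na_residue=3)
    return structure, na


@pytest.fixture(scope="session")
def toy_mesh(toy_structure):
    structure, _ = toy_structure
    return generate_surface(structure, grid_spacing=0.7)


@pytest.fixture(scope="session")
def unit_sphere():
    mesh, truth = make_canonical_mesh("sphere", resolution=3, size=1.0)
    return mesh, truth


@pytest.fixture(scope="session")
def sphere_r2():
    mesh, truth = make_canonical_mesh("sphere", resolution=4, size=2.0)
    return mesh, truth
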