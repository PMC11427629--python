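import numpy as np
import pytest

from surfbind.fixtures import make_canonical_mesh
from surfbind.mesh import (SurfaceMesh, compute_edge_features, compute_normals,
                           edge_geometry, generate_surface, read_mesh,
                           write_mesh)
from surfbind.structure import Atom, AtomicStructure

from conftest import random_rotation

ICOSAHEDRON_OFF = """OFF
12 20 0
0 0 2
1.788854 0 0.894427
0.552786 1.701302 0.894427
-1.447214 1.051462 0.894427
-1.447214 -1.051462 0.894427
0.552786 -1.701302 0.894427
1.447214 1.051462 -0.894427
-0.552786 1.701302 -0.894427
-1.788854 0 -0.894427
-0.552786 -1.701302 -0.894427
1.447214 -1.051462 -0.894427
0 0 -2
3 2 0 1
3 3 0 2
3 4 0 3
3 5 0 4
3 1 0 5
3 2 1 6
3 7 2 6
3 3 2 7
3 8 3 7
3 4 3 8
3 9 4 8
3 5 4 9
3 10 5 9
3 6 1 10
3 1 5 10
3 6 11 7
3 7 11 8
3 8 11 9
3 9 11 10
3 10 11 6
"""


def _atom(x, y, z, radius=1.5):
    return Atom(1, "C", "C", "ALA", 1, "A", x, y, z, radius=radius)


# ---------------------------------------------------------------------------
# surface generation


def test_single_atom_surface_area_matches_isosurface_radius():
    s = AtomicStructure([_atom(0, 0, 0)])
    mesh = generate_surface(s, grid_spacing=0.25)
    assert mesh.is_closed()
    # read the effective radius off the density crossing along +x
    from surfbind.mesh import _gaussian_density

    xs = np.linspace(0.5, 4.0, 2000)
    pts = np.column_stack([xs, np.zeros_like(xs), np.zeros_like(xs)])
    dens = _gaussian_density(pts, s.coords, s.radii, sigma=1.0)
    r_eff = xs[np.argmin(np.abs(dens - 1.0))]
    assert mesh.area() == pytest.approx(4 * np.pi * r_eff ** 2, rel=0.05)


def test_two_distant_atoms_make_two_components():
    s = AtomicStructure([_atom(0, 0, 0), _atom(50, 0, 0)])
    mesh = generate_surface(s, grid_spacing=0.5)
    assert len(np.unique(mesh.connected_components())) == 2


def test_two_close_atoms_make_one_component():
    s = AtomicStructure([_atom(0, 0, 0), _atom(1, 0, 0)])
    mesh = generate_surface(s, grid_spacing=0.4)
    assert len(np.unique(mesh.connected_components())) == 1


def test_degenerate_grid_spacing_errors():
    s = AtomicStructure([_atom(0, 0, 0)])
    with pytest.raises(ValueError):
        generate_surface(s, grid_spacing=50.0)


def test_generated_mesh_is_closed_genus_zero(toy_mesh):
    assert toy_mesh.is_closed()
    for comp in np.unique(toy_mesh.connected_components()):
        assert toy_mesh.euler_characteristic(comp) == 2


def test_vertex_residue_map_total(toy_mesh):
    assert toy_mesh.vertex_residue is not None
    assert len(toy_mesh.vertex_residue) == toy_mesh.n_vertices
    assert np.all(toy_mesh.vertex_residue >= 0)


# ---------------------------------------------------------------------------
# I/O


def test_icosahedron_off_fixture(tmp_path):
    p = tmp_path / "ico.off"
    p.write_text(ICOSAHEDRON_OFF)
    mesh = read_mesh(str(p))
    assert mesh.n_vertices == 12
    assert mesh.n_faces == 20
    assert mesh.is_closed()


@pytest.mark.parametrize("fmt", ["off", "ply"])
def test_mesh_round_trip(tmp_path, unit_sphere, fmt):
    mesh, _ = unit_sphere
    p = tmp_path / f"sphere.{fmt}"
    write_mesh(mesh, str(p), fmt=fmt)
    again = read_mesh(str(p))
    np.testing.assert_array_equal(again.F, mesh.F)
    np.testing.assert_allclose(again.V, mesh.V, atol=1e-6)


def test_quad_ply_rejected(tmp_path):
    ply = ("ply\nformat ascii 1.0\nelement vertex 4\n"
           "property float x\nproperty float y\nproperty float z\n"
           "element face 1\nproperty list uchar int vertex_indices\n"
           "end_header\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n4 0 1 2 3\n")
    p = tmp_path / "quad.ply"
    p.write_text(ply)
    with pytest.raises(ValueError, match="non-triangular"):
        read_mesh(str(p))


def test_quad_off_rejected(tmp_path):
    off = "OFF\n4 1 0\n0 0 0\n1 0 0\n1 1 0\n0 1 0\n4 0 1 2 3\n"
    p = tmp_path / "quad.off"
    p.write_text(off)
    with pytest.raises(ValueError, match="non-triangular"):
        read_mesh(str(p))


# ---------------------------------------------------------------------------
# normals


def test_sphere_normals_are_radial(unit_sphere):
    mesh, _ = unit_sphere
    radial = mesh.V / np.linalg.norm(mesh.V, axis=1, keepdims=True)
    cos = np.einsum("ij,ij->i", mesh.normals, radial)
    assert np.degrees(np.arccos(np.clip(cos, -1, 1))).max() < 2.0


def test_flat_fan_normals_parallel():
    V = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [-1, 0.5, 0]],
                 dtype=float)
    F = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 4]])
    mesh = compute_normals(SurfaceMesh(V, F), orient=False)
    assert np.allclose(np.abs(mesh.normals[:, 2]), 1.0)
    assert np.allclose(mesh.normals[:, :2], 0.0, atol=1e-12)


def test_inverted_orientation_is_fixed(unit_sphere):
    mesh, _ = unit_sphere
    flipped = SurfaceMesh(mesh.V.copy(), mesh.F[:, ::-1].copy())
    compute_normals(flipped)
    centered = flipped.V - flipped.V.mean(axis=0)
    assert np.all(np.einsum("ij,ij->i", flipped.normals, centered) > 0)


def test_zero_area_face_skipped_with_warning():
    V = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float)
    F = np.array([[0, 1, 2], [0, 0, 1]])
    with pytest.warns(UserWarning, match="zero-area"):
        compute_normals(SurfaceMesh(V, F), orient=False)


# ---------------------------------------------------------------------------
# edge features


def test_planar_patch_interior_edge_angles():
    mesh, truth = make_canonical_mesh("plane", resolution=10, size=10.0)
    ef = compute_edge_features(mesh)
    interior = truth["interior"]
    sel = np.isin(ef.edges[:, 0], interior) & np.isin(ef.edges[:, 1], interior)
    assert sel.any()
    np.testing.assert_allclose(ef.angle_normals[sel], 0.0, atol=1e-9)
    np.testing.assert_allclose(ef.angle_source[sel], 90.0, atol=1e-9)
    np.testing.assert_allclose(ef.angle_target[sel], 90.0, atol=1e-9)


def test_sphere_chord_normal_angle(unit_sphere):
    mesh, _ = unit_sphere
    ef = compute_edge_features(mesh)
    expected = np.degrees(2 * np.arcsin(ef.length / 2.0))
    assert np.abs(ef.angle_normals - expected).max() < 2.0


@pytest.mark.parametrize("seed", range(10))
def test_edge_features_rigid_motion_invariant(unit_sphere, seed):
    mesh, _ = unit_sphere
    ef0 = compute_edge_features(mesh).as_matrix()
    rng = np.random.default_rng(seed)
    Q = random_rotation(rng)
    moved = mesh.transformed(Q, rng.uniform(-20, 20, 3))
    ef1 = compute_edge_features(moved).as_matrix()
    np.testing.assert_allclose(ef1, ef0, atol=1e-5)


def test_coincident_endpoints_error():
    V = np.array([[0, 0, 0], [0, 0, 0]], dtype=float)
    normals = np.array([[0, 0, 1], [0, 0, 1]], dtype=float)
    with pytest.raises(ValueError, match="coincident"):
        edge_geometry(V, normals, np.array([[0, 1]]))


def test_edge_set_symmetric(unit_sphere):
    mesh, _ = unit_sphere
    ef = compute_edge_features(mesh)
    pairs = {tuple(e) for e in ef.edges}
    assert all((b, a) in pairs for a, b in pairs)
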