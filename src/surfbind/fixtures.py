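"""Synthetic data: canonical meshes, toy structures, planted datasets,
and brute-force oracles.

The planted dataset emulates the statistical structure of surface-mesh
training data: smooth, spatially correlated vertex features on a
protein-sized closed surface, with a designated feature group shifted inside
a contiguous surface patch.  Segmentation labels are patch membership;
classification labels are patch presence.  Everything is deterministic for
a fixed seed.  The brute-force oracles re-derive farthest-point sampling,
radial graphs, and half-ball circular variance directly from their
definitions, sharing no code with the fast implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .features import STRUCTURAL_FEATURES, FeatureTable
from .learning import GraphSample, LabelSet
from .mesh import SurfaceMesh, compute_normals
from .nn import LayerConfig, build_hierarchy
from .structure import Atom, AtomicStructure

__all__ = [
    "make_canonical_mesh", "make_toy_structure", "PlantedDatasetSpec",
    "make_planted_dataset", "planted_graph_samples", "cv_montecarlo",
    "fps_exhaustive", "radial_graph_bruteforce", "make_pssm_text",
    "make_hhm_text",
]


# ---------------------------------------------------------------------------
# canonical meshes with analytic ground truth


def _icosphere(subdivisions: int, radius: float) -> tuple[np.ndarray, np.ndarray]:
    import trimesh

    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return np.asarray(m.vertices, float), np.asarray(m.faces, int)


def _plane_patch(n: int, size: float) -> tuple[np.ndarray, np.ndarray]:
    """Uniform triangulated square grid of (n+1)^2 vertices in the z=0 plane."""
    xs = np.linspace(0.0, size, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    V = np.column_stack([X.ravel(), Y.ravel(), np.zeros((n + 1) ** 2)])
    F = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = a + 1
            c = a + (n + 1)
            d = c + 1
            F.append([a, b, d])
            F.append([a, d, c])
    return V, np.array(F, int)


def _cylinder(radius: float, height: float, sections: int,
              n_rings: int = 16) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed cylinder with ``n_rings + 1`` vertex rings along z and cap
    fans; returns (V, F, side_mask) where side_mask marks ring vertices not
    adjacent to the caps."""
    thetas = 2 * np.pi * np.arange(sections) / sections
    zs = np.linspace(-height / 2, height / 2, n_rings + 1)
    ring = np.column_stack([radius * np.cos(thetas), radius * np.sin(thetas)])
    V = np.vstack([
        np.column_stack([ring, np.full(sections, z)]) for z in zs
    ])
    F = []
    for k in range(n_rings):
        base = k * sections
        top = (k + 1) * sections
        for s in range(sections):
            s2 = (s + 1) % sections
            F.append([base + s, base + s2, top + s2])
            F.append([base + s, top + s2, top + s])
    bot_c = len(V)
    top_c = len(V) + 1
    V = np.vstack([V, [[0, 0, zs[0]], [0, 0, zs[-1]]]])
    for s in range(sections):
        s2 = (s + 1) % sections
        F.append([bot_c, s2, s])
        F.append([top_c, n_rings * sections + s, n_rings * sections + s2])
    side = np.zeros(len(V), dtype=bool)
    side[2 * sections:(n_rings - 1) * sections] = True
    return V, np.array(F, int), side


def make_canonical_mesh(shape: str, resolution: int = 3, size: float = 1.0,
                        pocket_depth: float = 0.0,
                        pocket_radius: float = 0.6) -> tuple[SurfaceMesh, dict]:
    """Build a canonical test mesh plus its analytic ground-truth record.

    Shapes: ``sphere`` (icosphere, size = radius), ``plane`` (open square
    patch, size = edge length), ``cylinder`` (closed, size = radius, height
    4*size), ``pocketed-sphere`` (icosphere with a smooth radial
    indentation of depth ``pocket_depth`` within angular radius
    ``pocket_radius`` of the +z pole).
    """
    truth: dict = {"shape": shape}
    if shape == "sphere":
        V, F = _icosphere(resolution, size)
        truth.update(mean_curvature=1.0 / size, area=4 * math.pi * size ** 2,
                     normals="radial", closed=True)
    elif shape == "plane":
        if resolution < 3:
            raise ValueError("plane needs resolution >= 3")
        V, F = _plane_patch(resolution, size)
        n = resolution
        interior = np.array([
            i * (n + 1) + j for i in range(1, n) for j in range(1, n)
        ])
        truth.update(mean_curvature=0.0, closed=False, interior=interior)
    elif shape == "cylinder":
        V, F, side = _cylinder(size, 4.0 * size, max(24, 8 * resolution))
        truth.update(mean_curvature=1.0 / (2.0 * size), side_vertices=side,
                     closed=True)
    elif shape == "pocketed-sphere":
        V, F = _icosphere(resolution, size)
        r = np.linalg.norm(V, axis=1)
        ang = np.arccos(np.clip(V[:, 2] / r, -1, 1))
        bump = np.where(ang < pocket_radius,
                        0.5 * (1 + np.cos(math.pi * ang / pocket_radius)), 0.0)
        V = V * (1.0 - pocket_depth * bump / size)[:, None]
        truth.update(closed=True, pocket_vertices=ang < pocket_radius)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    mesh = SurfaceMesh(V, F)
    compute_normals(mesh, orient=truth.get("closed", False))
    if shape == "plane":
        # open patch: orient all normals to +z
        flip = mesh.normals[:, 2] < 0
        mesh.normals[flip] *= -1.0
    return mesh, truth


# ---------------------------------------------------------------------------
# toy structures


_RES_CYCLE = ("ALA", "ARG", "ASP", "LEU", "SER", "LYS", "GLU", "PHE", "GLY",
              "THR")
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN = math.radians(100.0)


def make_toy_structure(n_residues: int, seed: int = 0,
                       na_offset: float | None = None,
                       na_residue: int = 0) -> tuple[AtomicStructure, np.ndarray]:
    """Helix-like toy protein with N/CA/C/O/CB atoms per residue.

    Returns the structure and a (possibly empty) set of fake nucleic-acid
    atom coordinates placed ``na_offset`` Angstrom from residue
    ``na_residue``'s CB atom along the outward helix normal.  Coordinates
    are rounded to 1e-3 A so PDB serialization round-trips losslessly.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    atoms: list[Atom] = []
    serial = 1
    cb_positions = []
    for i in range(n_residues):
        theta = i * _HELIX_TURN
        z = i * _HELIX_RISE
        ca = np.array([_HELIX_RADIUS * math.cos(theta),
                       _HELIX_RADIUS * math.sin(theta), z])
        outward = np.array([math.cos(theta), math.sin(theta), 0.0])
        res = _RES_CYCLE[i % len(_RES_CYCLE)]
        offsets = {
            "N": ca + np.array([-0.8, 0.6, -0.9]),
            "CA": ca,
            "C": ca + np.array([0.9, -0.4, 0.8]),
            "O": ca + np.array([1.2, -1.3, 1.0]),
            "CB": ca + 1.5 * outward,
        }
        jitter = rng.normal(scale=0.05, size=(len(offsets), 3))
        for k, (name, pos) in enumerate(offsets.items()):
            p = np.round(pos + jitter[k], 3)
            element = name[0]
            atoms.append(Atom(serial, name, element, res, i + 1, "A",
                              float(p[0]), float(p[1]), float(p[2]),
                              radius=1.7 if element == "C" else 1.5))
            serial += 1
        cb_positions.append(offsets["CB"])
    structure = AtomicStructure(atoms)
    # reuse the radius table conventions of load_structure
    from .structure import DEFAULT_RADIUS_TABLE

    for a in structure.atoms:
        a.radius = DEFAULT_RADIUS_TABLE.get(a.element, 1.7)
        if a.radius <= 0:
            a.radius = 0.6
    na = np.zeros((0, 3))
    if na_offset is not None:
        cb = cb_positions[na_residue]
        direction = np.array([math.cos(na_residue * _HELIX_TURN),
                              math.sin(na_residue * _HELIX_TURN), 0.0])
        na = np.round((cb + na_offset * direction), 3)[None, :]
    return structure, na


# ---------------------------------------------------------------------------
# planted datasets


@dataclass
class PlantedDatasetSpec:
    """Study conditions for the planted-signal experiments.

    Defaults describe a small protein-domain-sized surface: ~642-vertex
    icospheres of radius 16 A, a contiguous patch of geodesic radius 15 A
    (~20% of the surface, a typical binding-footprint fraction), and a +2 SD
    shift of the electrostatics feature group inside the patch on top of
    smooth unit-variance correlated noise.
    """

    n_meshes: int = 50
    subdivisions: int = 3           # icosphere level; 3 -> 642 vertices
    sphere_radius: float = 16.0
    patch_radius: float = 15.0      # geodesic, Angstrom
    affected_features: tuple[str, ...] = ("PH1", "PH2")
    effect_size: float = 2.0        # in units of the noise SD
    noise_sd: float = 1.0
    class_balance: float = 0.5      # fraction of meshes carrying a patch
                                    # (classification task only)
    smoothing_rounds: int = 3
    seed: int = 0
    task: str = "segmentation"      # or "classification"

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        frac = self.patch_fraction
        if not (0.0 < frac < 0.5):
            raise ValueError(
                f"patch fraction {frac:.3f} outside (0, 0.5): patch larger "
                "than a hemisphere"
            )
        unknown = set(self.affected_features) - set(STRUCTURAL_FEATURES)
        if unknown:
            raise ValueError(f"unknown affected features: {sorted(unknown)}")

    @property
    def patch_fraction(self) -> float:
        theta = self.patch_radius / self.sphere_radius
        return (1.0 - math.cos(theta)) / 2.0


def _smooth(X: np.ndarray, F: np.ndarray, rounds: int) -> np.ndarray:
    from scipy import sparse

    n = len(X)
    e = np.vstack([F[:, [0, 1]], F[:, [1, 2]], F[:, [2, 0]]])
    A = sparse.coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])),
                          shape=(n, n)).maximum(0).tocsr()
    A = ((A + A.T) > 0).astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel() + 1.0
    for _ in range(rounds):
        X = (X + A @ X) / deg[:, None]
    return X


def make_planted_dataset(spec: PlantedDatasetSpec) -> list[dict]:
    """Generate the planted dataset.

    Returns one record per mesh with keys ``mesh`` (SurfaceMesh, normals
    set), ``features`` (FeatureTable over the 18 structural columns),
    ``labels`` (LabelSet), and ``patch`` (boolean vertex mask).
    """
    rng = np.random.default_rng(spec.seed)
    base_V, F = _icosphere(spec.subdivisions, spec.sphere_radius)
    cols = STRUCTURAL_FEATURES
    affected = [cols.index(c) for c in spec.affected_features]
    out: list[dict] = []
    for m in range(spec.n_meshes):
        # random rigid attitude per mesh
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        V = base_V @ Q.T
        mesh = SurfaceMesh(V, F.copy())
        compute_normals(mesh)
        X = rng.normal(size=(len(V), len(cols)))
        X = _smooth(X, F, spec.smoothing_rounds)
        sd = X.std(axis=0, keepdims=True)
        X = X / np.maximum(sd, 1e-9) * spec.noise_sd
        if spec.task == "classification":
            has_patch = rng.random() < spec.class_balance
        else:
            has_patch = True
        patch = np.zeros(len(V), dtype=bool)
        if has_patch:
            # area-uniform patch centre (a random vertex would bias patches
            # toward the denser regions of the icosphere triangulation)
            u = rng.normal(size=3)
            center = spec.sphere_radius * u / np.linalg.norm(u)
            cosang = (V @ center) / (spec.sphere_radius ** 2)
            ang = np.arccos(np.clip(cosang, -1, 1))
            patch = ang * spec.sphere_radius <= spec.patch_radius
            X[np.ix_(patch, affected)] += spec.effect_size * spec.noise_sd
        labels = LabelSet(vertex_labels=patch.astype(int),
                          mesh_label=int(has_patch))
        out.append({
            "mesh": mesh,
            "features": FeatureTable(X, cols),
            "labels": labels,
            "patch": patch,
        })
    return out


def planted_graph_samples(records: list[dict],
                          config: LayerConfig | None = None) -> list[GraphSample]:
    """Precompute graph hierarchies for the planted records."""
    config = config or LayerConfig()
    return [
        GraphSample(build_hierarchy(r["mesh"], config), r["features"].values,
                    r["labels"])
        for r in records
    ]


# ---------------------------------------------------------------------------
# brute-force oracles (tests only; independent of the fast paths)


def cv_montecarlo(point_config: str | np.ndarray, radius: float = 1.0,
                  n_samples: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo circular variance at the origin.

    ``point_config`` is either an (n, 3) array of occupying points, or one of
    ``"ball"`` / ``"half-ball"`` for uniform samples in the (half-)ball of
    ``radius`` around the origin (half-ball: z >= 0).
    """
    rng = np.random.default_rng(seed)
    if isinstance(point_config, str):
        pts = rng.normal(size=(n_samples, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= radius * rng.random(n_samples)[:, None] ** (1.0 / 3.0)
        if point_config == "half-ball":
            pts[:, 2] = np.abs(pts[:, 2])
        elif point_config != "ball":
            raise ValueError(f"unknown configuration {point_config!r}")
    else:
        pts = np.asarray(point_config, float)
        pts = pts[np.linalg.norm(pts, axis=1) <= radius]
    norms = np.linalg.norm(pts, axis=1)
    keep = norms > 1e-12
    u = pts[keep] / norms[keep, None]
    if not len(u):
        return 0.0
    return float(1.0 - np.linalg.norm(u.sum(axis=0)) / len(u))


def fps_exhaustive(V: np.ndarray, ratio: float, start: int = 0) -> list[int]:
    """Greedy farthest-point sampling by direct definition (python loops)."""
    V = np.asarray(V, float)
    n = len(V)
    m = math.ceil(ratio * n)
    selected = [start]
    while len(selected) < m:
        best_i, best_d = None, -1.0
        for i in range(n):
            if i in selected:
                continue
            d = min(float(np.linalg.norm(V[i] - V[j])) for j in selected)
            if d > best_d:  # strict: keeps the lowest tied index
                best_i, best_d = i, d
        selected.append(best_i)
    return selected


def radial_graph_bruteforce(V: np.ndarray, centroids: np.ndarray,
                            radius: float) -> set[tuple[int, int]]:
    """All (source j, centroid position i) pairs with ||V_j - V_c|| <= r,
    j != c, by double loop."""
    V = np.asarray(V, float)
    out: set[tuple[int, int]] = set()
    for i, c in enumerate(centroids):
        for j in range(len(V)):
            if j == c:
                continue
            if float(np.linalg.norm(V[j] - V[c])) <= radius:
                out.add((j, i))
    return out


# ---------------------------------------------------------------------------
# profile-file fixtures


def make_pssm_text(scores: np.ndarray, sequence: str) -> str:
    """Render a PSI-BLAST-style ascii PSSM for the given (n, 20) log-odds."""
    aa = "ARNDCQEGHILKMFPSTWYV"
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(aa) + "    " + "   ".join(aa),
    ]
    for i, (ch, row) in enumerate(zip(sequence, scores), start=1):
        nums = " ".join(f"{int(v):3d}" for v in row)
        pct = " ".join(f"{0:3d}" for _ in row)
        lines.append(f"{i:5d} {ch}  {nums}  {pct}  0.00 0.00")
    return "\n".join(lines) + "\n"


def make_hhm_text(emissions: np.ndarray, sequence: str) -> str:
    """Render a minimal HHblits .hhm with the given (n, 20) emission
    probabilities (0 encoded as '*')."""

    def code(p: float) -> str:
        if p <= 0:
            return "*"
        return str(int(round(-1000.0 * math.log2(p))))

    lines = ["HHsearch 1.5", "NAME  fixture", "LENG  %d" % len(sequence),
             "HMM    A\tC\tD\tE\tF\tG\tH\tI\tK\tL\tM\tN\tP\tQ\tR\tS\tT\tV\tW\tY",
             "       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\tNeff_I\tNeff_D",
             "       0\t*\t*\t0\t*\t0\t*\t*\t*\t*"]
    for i, (ch, row) in enumerate(zip(sequence, emissions), start=1):
        em = "\t".join(code(p) for p in row)
        lines.append(f"{ch} {i}\t{em}\t{i}")
        lines.append("\t0\t*\t*\t*\t*\t*\t*\t1000\t0\t0")
        lines.append("")
    lines.append("//")
    return "\n".join(lines) + "\n"
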