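"""Chemical and electrostatic vertex features.

Residue- and atom-level descriptors (Atchley factors, hydrogen-bond
donor/acceptor flags, spatial aggregation propensity, screened-Coulomb
electrostatics) are computed at their native resolution and mapped onto mesh
vertices by inverse-distance weighting within a 2.5 A cutoff, with a
nearest-atom fallback for vertices that sit farther from every atom.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .mesh import ATOM_VERTEX_CUTOFF, SurfaceMesh
from .structure import AtomicStructure

__all__ = [
    "ATCHLEY_FACTORS",
    "map_atom_to_vertices",
    "atchley_features",
    "hbond_features",
    "sap_feature",
    "electrostatics",
]

# Five physicochemical factors per amino acid (polarity/accessibility,
# secondary-structure propensity, molecular size, codon composition, charge).
ATCHLEY_FACTORS: dict[str, tuple[float, float, float, float, float]] = {
    "ALA": (-0.591, -1.302, -0.733, 1.570, -0.146),
    "CYS": (-1.343, 0.465, -0.862, -1.020, -0.255),
    "ASP": (1.050, 0.302, -3.656, -0.259, -3.242),
    "GLU": (1.357, -1.453, 1.477, 0.113, -0.837),
    "PHE": (-1.006, -0.590, 1.891, -0.397, 0.412),
    "GLY": (-0.384, 1.652, 1.330, 1.045, 2.064),
    "HIS": (0.336, -0.417, -1.673, -1.474, -0.078),
    "ILE": (-1.239, -0.547, 2.131, 0.393, 0.816),
    "LYS": (1.831, -0.561, 0.533, -0.277, 1.648),
    "LEU": (-1.019, -0.987, -1.505, 1.266, -0.912),
    "MET": (-0.663, -1.524, 2.219, -1.005, 1.212),
    "ASN": (0.945, 0.828, 1.299, -0.169, 0.933),
    "PRO": (0.189, 2.081, -1.628, 0.421, -1.392),
    "GLN": (0.931, -0.179, -3.005, -0.503, -1.853),
    "ARG": (1.538, -0.055, 1.502, 0.440, 2.897),
    "SER": (-0.228, 1.399, -4.760, 0.670, -2.647),
    "THR": (-0.032, 0.326, 2.213, 0.908, 1.313),
    "VAL": (-1.337, -0.279, -0.544, 1.242, -1.262),
    "TRP": (-0.595, 0.009, 0.672, -2.128, -0.184),
    "TYR": (0.260, 0.830, 3.097, -0.838, 1.512),
}

# Hydrogen-bond capable heavy atoms, keyed by (residue, atom name);
# "*" matches any residue (backbone).
_HB_ACCEPTORS: set[tuple[str, str]] = {
    ("*", "O"), ("*", "OXT"),
    ("ASN", "OD1"), ("GLN", "OE1"),
    ("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("MET", "SD"),
}
_HB_DONORS: set[tuple[str, str]] = {
    ("*", "N"),
    ("ASN", "ND2"), ("GLN", "NE2"),
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
    ("HIS", "ND1"), ("HIS", "NE2"),
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("TRP", "NE1"), ("CYS", "SG"),
}

# Black-Mould-type hydrophobicity, normalized to [0, 1]; SAP centres it on
# glycine so polar residues contribute negatively and aliphatic/aromatic
# residues positively.
_HYDROPHOBICITY: dict[str, float] = {
    "ALA": 0.616, "ARG": 0.000, "ASN": 0.236, "ASP": 0.028, "CYS": 0.680,
    "GLN": 0.251, "GLU": 0.043, "GLY": 0.501, "HIS": 0.165, "ILE": 0.943,
    "LEU": 0.943, "LYS": 0.283, "MET": 0.738, "PHE": 1.000, "PRO": 0.711,
    "SER": 0.359, "THR": 0.450, "TRP": 0.878, "TYR": 0.880, "VAL": 0.825,
}

# Approximate maximum side-chain solvent accessibility (A^2) in an extended
# Gly-X-Gly context, used to normalize side-chain exposure.
_MAX_SIDECHAIN_SASA: dict[str, float] = {
    "ALA": 67.0, "ARG": 196.0, "ASN": 113.0, "ASP": 106.0, "CYS": 104.0,
    "GLN": 144.0, "GLU": 138.0, "GLY": 1.0, "HIS": 151.0, "ILE": 140.0,
    "LEU": 137.0, "LYS": 167.0, "MET": 160.0, "PHE": 175.0, "PRO": 105.0,
    "SER": 80.0, "THR": 102.0, "TRP": 217.0, "TYR": 187.0, "VAL": 117.0,
}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA"}


def map_atom_to_vertices(structure: AtomicStructure, mesh: SurfaceMesh,
                         per_atom: np.ndarray,
                         cutoff: float = ATOM_VERTEX_CUTOFF) -> np.ndarray:
    """Inverse-distance weighted average of per-atom values onto vertices.

    ``v = sum_a f_a / d(v,a) / sum_a 1 / d(v,a)`` over atoms within
    ``cutoff``; a vertex coincident with an atom centre copies that atom's
    value; a vertex with no atom in range takes its nearest atom's value.
    """
    per_atom = np.asarray(per_atom, dtype=float)
    if not np.all(np.isfinite(per_atom)):
        raise ValueError("per-atom values must be finite")
    squeeze = per_atom.ndim == 1
    vals = per_atom.reshape(len(per_atom), -1)
    coords = structure.coords
    tree = cKDTree(coords)
    out = np.empty((mesh.n_vertices, vals.shape[1]), dtype=float)
    neighbors = tree.query_ball_point(mesh.V, r=cutoff)
    _, nearest = tree.query(mesh.V)
    for i, idx in enumerate(neighbors):
        if not idx:
            out[i] = vals[nearest[i]]
            continue
        d = np.linalg.norm(coords[idx] - mesh.V[i], axis=1)
        if d.min() < 1e-6:
            out[i] = vals[idx[int(np.argmin(d))]]
            continue
        w = 1.0 / d
        out[i] = (w[:, None] * vals[idx]).sum(axis=0) / w.sum()
    return out[:, 0] if squeeze else out.reshape((mesh.n_vertices,) + per_atom.shape[1:])


def atchley_features(structure: AtomicStructure) -> np.ndarray:
    """Per-atom (n, 5) Atchley factors broadcast residue -> child atoms;
    nonstandard residues get zeros with a warning."""
    out = np.zeros((len(structure), 5))
    warned: set[str] = set()
    for i, a in enumerate(structure.atoms):
        row = ATCHLEY_FACTORS.get(a.res_name)
        if row is None:
            if a.res_name not in warned:
                warnings.warn(f"nonstandard residue {a.res_name}: zero Atchley factors")
                warned.add(a.res_name)
            continue
        out[i] = row
    return out


def hbond_features(structure: AtomicStructure) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom hydrogen-bond acceptor/donor indicator vectors (0/1)."""
    hba = np.zeros(len(structure))
    hbd = np.zeros(len(structure))
    for i, a in enumerate(structure.atoms):
        if (a.res_name, a.name) in _HB_ACCEPTORS or ("*", a.name) in _HB_ACCEPTORS:
            hba[i] = 1.0
        if (a.res_name, a.name) in _HB_DONORS or ("*", a.name) in _HB_DONORS:
            hbd[i] = 1.0
    return hba, hbd


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate coordinates into a principal-axes frame with moment-fixed
    signs, so downstream point-grid algorithms (Shrake-Rupley) give
    rigid-motion-invariant results."""
    c = coords - coords.mean(axis=0)
    if len(c) < 3:
        return c
    _, vecs = np.linalg.eigh(np.cov(c.T))
    vecs = vecs[:, ::-1]  # descending variance
    proj = c @ vecs
    for k in range(3):
        m3 = (proj[:, k] ** 3).sum()
        if m3 < 0:
            vecs[:, k] *= -1
    frame = vecs
    if np.linalg.det(frame) < 0:
        frame[:, 2] *= -1
    return c @ frame


def _shrake_rupley_sasa(structure: AtomicStructure) -> np.ndarray:
    """Per-atom solvent-accessible surface area via biotite (A^2),
    evaluated in a canonical frame for rigid-motion invariance."""
    import biotite.structure as bst

    arr = bst.AtomArray(len(structure))
    arr.coord = _canonical_frame(structure.coords)
    arr.chain_id = np.array([a.chain_id for a in structure.atoms])
    arr.res_id = np.array([a.res_seq for a in structure.atoms])
    arr.res_name = np.array([a.res_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.hetero = np.array([a.hetero for a in structure.atoms])
    sasa = bst.sasa(arr, vdw_radii="Single", point_number=240)
    return np.nan_to_num(np.asarray(sasa, dtype=float))


def sap_feature(structure: AtomicStructure, radius: float = 5.0,
                sasa: np.ndarray | None = None) -> np.ndarray:
    """Spatial aggregation propensity per atom.

    ``SAP(a) = sum over side-chain atoms b within ``radius`` of a of
    hydrophobicity(res(b)) x relative side-chain exposure(res(b))``, with
    hydrophobicity centred on glycine and exposure the residue side-chain
    SASA over its maximum reference value (clipped to [0, 1]).  Fully buried
    side chains contribute nothing.
    """
    if sasa is None:
        sasa = _shrake_rupley_sasa(structure)
    res_idx = structure.residue_index
    n_res = structure.n_residues
    sc_mask = np.array(
        [a.name not in _BACKBONE_NAMES and not a.element == "H"
         for a in structure.atoms]
    )
    sc_sasa = np.zeros(n_res)
    np.add.at(sc_sasa, res_idx[sc_mask], sasa[sc_mask])
    res_names = [rid[2] for rid in structure.residue_ids]
    rel = np.zeros(n_res)
    hyd = np.zeros(n_res)
    g = _HYDROPHOBICITY["GLY"]
    for r, name in enumerate(res_names):
        ref = _MAX_SIDECHAIN_SASA.get(name)
        if ref is None:
            continue
        rel[r] = np.clip(sc_sasa[r] / ref, 0.0, 1.0)
        hyd[r] = _HYDROPHOBICITY[name] - g
    contrib = hyd[res_idx] * rel[res_idx]   # per-atom term
    contrib[~sc_mask] = 0.0
    coords = structure.coords
    tree = cKDTree(coords[sc_mask])
    sc_contrib = contrib[sc_mask]
    out = np.zeros(len(structure))
    for i, idx in enumerate(tree.query_ball_point(coords, r=radius)):
        if idx:
            out[i] = sc_contrib[idx].sum()
    return out


# Coulomb constant e^2/(4 pi eps0) in kcal*A/(mol*e^2)
_KE = 332.0636


def electrostatics(structure: AtomicStructure, mesh: SurfaceMesh,
                   ionic_strength: float = 0.15, eps_interior: float = 2.0,
                   eps_solvent: float = 78.5) -> tuple[np.ndarray, np.ndarray]:
    """Screened-Coulomb (Debye-Hueckel) potential PH1 and outward-normal
    field component PH2 at the mesh vertices.

    ``phi(x) = (k_e / eps) sum_i q_i exp(-kappa d_i) / d_i`` with the inverse
    Debye length ``kappa = sqrt(I) / 3.04`` per Angstrom at 298 K and the
    solvent dielectric as the effective uniform medium; ``PH2 = -grad(phi).n``
    with outward unit normals.  ``eps_interior`` is recorded for provenance
    and for imported boundary-integral solutions; the uniform-medium model
    here does not use it.  Distances are clamped at 0.1 A.
    """
    if mesh.normals is None:
        raise ValueError("mesh has no normals")
    kappa = np.sqrt(max(ionic_strength, 0.0)) / 3.04
    q = structure.charges
    centers = structure.coords
    phi = np.zeros(mesh.n_vertices)
    field = np.zeros((mesh.n_vertices, 3))
    charged = np.nonzero(q != 0.0)[0]
    pref = _KE / eps_solvent
    for j in charged:
        d = mesh.V - centers[j]
        r = np.maximum(np.linalg.norm(d, axis=1), 0.1)
        screen = np.exp(-kappa * r)
        phi += pref * q[j] * screen / r
        # grad phi = -q pref e^{-kr}(kr+1)/r^3 * (x - x_j)
        field += (-pref * q[j] * screen * (kappa * r + 1.0) / r ** 3)[:, None] * d
    ph2 = -np.einsum("ij,ij->i", field, mesh.normals)
    return phi, ph2
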