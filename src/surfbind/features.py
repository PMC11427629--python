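"""Assembly of the per-vertex feature table.

Eighteen structure-based features are computed from the structure and mesh:
electrostatics (PH1, PH2), Atchley factors (AF1-AF5), hydrophobicity (SAP),
hydrogen-bonding (HBA, HBD), burial (CV1-CV3), mean curvature (MC), and heat
kernel signatures (HK1-HK4).  When PSSM/HHM profile files are supplied, 50
MSA features (PSSM1-20, HMM1-30) are appended; binding-function models use
the 18 structural features only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemistry, geometry
from .mesh import SurfaceMesh
from .profiles import ResidueProfile, align_profile
from .structure import AtomicStructure

__all__ = ["FeatureTable", "STRUCTURAL_FEATURES", "MSA_FEATURES",
           "FEATURE_GROUPS", "compute_features"]

STRUCTURAL_FEATURES: tuple[str, ...] = (
    "PH1", "PH2",
    "AF1", "AF2", "AF3", "AF4", "AF5",
    "SAP", "HBA", "HBD",
    "CV1", "CV2", "CV3",
    "MC",
    "HK1", "HK2", "HK3", "HK4",
)
MSA_FEATURES: tuple[str, ...] = tuple(f"PSSM{i}" for i in range(1, 21)) + tuple(
    f"HMM{i}" for i in range(1, 31)
)

#: feature groups used for grouped permutation importance
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "EP": ("PH1", "PH2"),
    "AF": ("AF1", "AF2", "AF3", "AF4", "AF5"),
    "SAP": ("SAP",),
    "HB": ("HBA", "HBD"),
    "CV": ("CV1", "CV2", "CV3"),
    "MC": ("MC",),
    "HKS": ("HK1", "HK2", "HK3", "HK4"),
}


@dataclass
class FeatureTable:
    """Named per-vertex feature matrix with per-column provenance."""

    values: np.ndarray                       # (N, F)
    columns: tuple[str, ...]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.columns = tuple(self.columns)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values shape does not match columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains NaN/Inf")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def select(self, names: tuple[str, ...]) -> "FeatureTable":
        idx = [self.columns.index(n) for n in names]
        return FeatureTable(self.values[:, idx], names,
                            {n: self.provenance.get(n, "computed") for n in names})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))

    def to_tsv(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df.to_numpy(float), tuple(df.columns),
                   {c: "imported" for c in df.columns})


def compute_features(structure: AtomicStructure, mesh: SurfaceMesh,
                     pssm: ResidueProfile | None = None,
                     hhm: ResidueProfile | None = None,
                     ionic_strength: float = 0.15,
                     eps_interior: float = 2.0,
                     eps_solvent: float = 78.5,
                     sap_radius: float = 5.0,
                     n_eigen: int = 64,
                     imported_potential: np.ndarray | None = None) -> FeatureTable:
    """Compute the full per-vertex feature table for one structure/mesh.

    Per-vertex electrostatics can be replaced by imported external-solver
    values (``imported_potential`` of shape (N, 2) for PH1/PH2), in which
    case the provenance for those columns is marked ``imported``.
    """
    if mesh.normals is None:
        raise ValueError("mesh needs normals")
    if mesh.vertex_residue is None:
        raise ValueError("mesh needs vertex->residue map")
    n = mesh.n_vertices
    cols: list[str] = []
    mats: list[np.ndarray] = []
    prov: dict[str, str] = {}

    if imported_potential is not None:
        ph = np.asarray(imported_potential, float).reshape(n, 2)
        prov.update({"PH1": "imported", "PH2": "imported"})
    else:
        ph1, ph2 = chemistry.electrostatics(structure, mesh, ionic_strength,
                                            eps_interior, eps_solvent)
        ph = np.column_stack([ph1, ph2])
        prov.update({"PH1": "computed", "PH2": "computed"})
    cols += ["PH1", "PH2"]
    mats.append(ph)

    af_atom = chemistry.atchley_features(structure)
    af = chemistry.map_atom_to_vertices(structure, mesh, af_atom)
    cols += ["AF1", "AF2", "AF3", "AF4", "AF5"]
    mats.append(af)

    sap_atom = chemistry.sap_feature(structure, radius=sap_radius)
    sap = chemistry.map_atom_to_vertices(structure, mesh, sap_atom)
    cols.append("SAP")
    mats.append(sap[:, None])

    hba_atom, hbd_atom = chemistry.hbond_features(structure)
    hba = chemistry.map_atom_to_vertices(structure, mesh, hba_atom)
    hbd = chemistry.map_atom_to_vertices(structure, mesh, hbd_atom)
    cols += ["HBA", "HBD"]
    mats.append(np.column_stack([np.clip(hba, 0, 1), np.clip(hbd, 0, 1)]))

    cv = np.column_stack([
        geometry.circular_variance(mesh, structure, r) for r in geometry.CV_RADII
    ])
    cols += ["CV1", "CV2", "CV3"]
    mats.append(cv)

    mc = geometry.mean_curvature(mesh)
    cols.append("MC")
    mats.append(mc[:, None])

    hks = geometry.heat_kernel_signature(mesh, n_eigen=n_eigen, normalize=True)
    cols += ["HK1", "HK2", "HK3", "HK4"]
    mats.append(hks)

    for c in cols:
        prov.setdefault(c, "computed")

    if pssm is not None:
        vals = align_profile(pssm, int(mesh.vertex_residue.max()) + 1
                             if structure is None else structure.n_residues)
        pv = vals[mesh.vertex_residue]
        cols += [f"PSSM{i}" for i in range(1, 21)]
        mats.append(pv)
        prov.update({f"PSSM{i}": "parsed" for i in range(1, 21)})
    if hhm is not None:
        vals = align_profile(hhm, structure.n_residues)
        hv = vals[mesh.vertex_residue]
        cols += [f"HMM{i}" for i in range(1, 31)]
        mats.append(hv)
        prov.update({f"HMM{i}": "parsed" for i in range(1, 31)})

    return FeatureTable(np.hstack(mats), tuple(cols), prov)
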