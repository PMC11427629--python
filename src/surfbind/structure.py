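"""Atomic structures: PDB parsing, radius and charge assignment.

The unit of input is a protein structure in PDB format.  Only ATOM/HETATM
records are consumed; waters are dropped.  Van der Waals radii follow an
AMBER-ff99-style per-element table, with the convention that any hydrogen
whose table radius is zero is assigned a minimum radius of 0.6 A so that it
still contributes to the molecular surface.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "AtomicStructure",
    "PDBParseError",
    "DEFAULT_RADIUS_TABLE",
    "load_structure",
    "write_pdb",
]


class PDBParseError(ValueError):
    """Raised when an ATOM/HETATM record cannot be parsed."""


#: Per-element van der Waals radii in Angstrom (AMBER-ff99-like).  Hydrogen is
#: listed as 0.0 and promoted to the 0.6 A floor at assignment time.
DEFAULT_RADIUS_TABLE: dict[str, float] = {
    "H": 0.0,
    "C": 1.700,
    "N": 1.625,
    "O": 1.480,
    "S": 1.782,
    "P": 1.871,
    "F": 1.750,
    "CL": 1.948,
    "BR": 2.220,
    "I": 2.350,
    "FE": 1.200,
    "ZN": 1.100,
    "MG": 0.787,
    "CA": 1.367,
    "NA": 1.868,
    "K": 2.658,
    "MN": 1.200,
    "SE": 1.900,
}

_FALLBACK_RADIUS = 1.7  # generic heavy-atom radius for unknown elements
_MIN_H_RADIUS = 0.6

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

# Simplified ionizable-group partial charges (units of e) keyed by
# (residue name, atom name).  Charge is split over symmetry-equivalent atoms.
_CHARGE_TABLE: dict[tuple[str, str], float] = {
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
    ("LYS", "NZ"): 1.0,
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
    # nucleic-acid backbone phosphate
    ("*", "OP1"): -0.5,
    ("*", "OP2"): -0.5,
    ("*", "O1P"): -0.5,
    ("*", "O2P"): -0.5,
}


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    x: float
    y: float
    z: float
    radius: float = 0.0
    charge: float = 0.0
    hetero: bool = False

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class AtomicStructure:
    """A parsed structure: atoms plus residue/chain bookkeeping.

    ``residue_index`` maps every atom position to a dense residue index;
    ``residue_ids`` lists the distinct ``(chain, res_seq, res_name)`` keys in
    order of first appearance.
    """

    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    @property
    def residue_ids(self) -> list[tuple[str, int, str]]:
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.res_seq, a.res_name), None)
        return list(seen)

    @property
    def residue_index(self) -> np.ndarray:
        """Dense residue index per atom (total mapping)."""
        order: dict[tuple[str, int, str], int] = {}
        idx = np.empty(len(self.atoms), dtype=int)
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.res_seq, a.res_name)
            idx[i] = order.setdefault(key, len(order))
        return idx

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def chain_filter(self, chain_id: str) -> "AtomicStructure":
        return AtomicStructure([a for a in self.atoms if a.chain_id == chain_id])

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "AtomicStructure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = []
        for a in self.atoms:
            p = R @ a.coord + t
            out.append(
                Atom(a.serial, a.name, a.element, a.res_name, a.res_seq,
                     a.chain_id, p[0], p[1], p[2], a.radius, a.charge, a.hetero)
            )
        return AtomicStructure(out)


def _guess_element(atom_name: str, columns_77_78: str) -> str:
    el = columns_77_78.strip().upper()
    if el:
        return el
    name = atom_name.strip()
    # leading digits (e.g. 1HB2) indicate hydrogens in some dialects
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in DEFAULT_RADIUS_TABLE and stripped[:2].upper() not in {"CA", "NA"}:
        return stripped[:2].upper()
    return stripped[0].upper()


def _assign_charge(res_name: str, atom_name: str) -> float:
    q = _CHARGE_TABLE.get((res_name, atom_name))
    if q is None:
        q = _CHARGE_TABLE.get(("*", atom_name), 0.0)
    return q


def load_structure(pdb_text: str, radius_table: dict[str, float] | None = None,
                   include_hetero: bool = True) -> AtomicStructure:
    """Parse PDB-format text into an :class:`AtomicStructure`.

    Radii come from ``radius_table`` (element keyed, Angstrom); hydrogens with
    a table radius of zero get the 0.6 A minimum.  Waters are excluded.
    Malformed ATOM/HETATM records raise :class:`PDBParseError` naming the line.
    """
    table = dict(DEFAULT_RADIUS_TABLE if radius_table is None else radius_table)
    atoms: list[Atom] = []
    for lineno, line in enumerate(io.StringIO(pdb_text), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"line {lineno}: record too short for coordinates")
        try:
            serial = int(line[6:11])
        except ValueError:
            serial = len(atoms) + 1
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain_id = line[21].strip() or "A"
        try:
            res_seq = int(line[22:26])
        except ValueError as e:
            raise PDBParseError(f"line {lineno}: bad residue number {line[22:26]!r}") from e
        try:
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as e:
            raise PDBParseError(f"line {lineno}: non-numeric coordinate") from e
        if not np.all(np.isfinite([x, y, z])):
            raise PDBParseError(f"line {lineno}: non-finite coordinate")
        if res_name in _WATER_NAMES:
            continue
        hetero = rec == "HETATM"
        if hetero and not include_hetero:
            continue
        element = _guess_element(name, line[76:78] if len(line) >= 78 else "")
        if element in table:
            radius = table[element]
        else:
            warnings.warn(
                f"line {lineno}: unknown element {element!r} for atom {name}; "
                f"using fallback radius {_FALLBACK_RADIUS} A"
            )
            radius = _FALLBACK_RADIUS
        if element == "H" and radius <= 0.0:
            radius = _MIN_H_RADIUS
        if radius <= 0.0:
            radius = _FALLBACK_RADIUS
        atoms.append(
            Atom(serial, name, element, res_name, res_seq, chain_id,
                 x, y, z, radius, _assign_charge(res_name, name), hetero)
        )
    if not atoms:
        raise PDBParseError("no ATOM/HETATM records found")
    return AtomicStructure(atoms)


def write_pdb(structure: AtomicStructure, bfactors: np.ndarray | None = None) -> str:
    """Serialize to PDB text, optionally stamping per-atom B-factors."""
    lines = []
    for i, a in enumerate(structure.atoms):
        rec = "HETATM" if a.hetero else "ATOM"
        b = 0.0 if bfactors is None else float(bfactors[i])
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        lines.append(
            f"{rec:<6s}{a.serial:>5d} {name:<4s} {a.res_name:>3s} "
            f"{a.chain_id:1s}{a.res_seq:>4d}    "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.00:6.2f}{b:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
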