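"""Parsers for sequence-profile files: PSI-BLAST ascii PSSMs and HHblits
profile HMMs.

The search tools themselves are never executed here; their output files are
parsed and the per-residue rows aligned to the residues of a target chain.
PSSM log-odds scores are squashed to (0, 1) with a logistic transform; HHM
integer codes are decoded to probabilities via ``p = 2^(-code / 1000)``
(``*`` decodes to 0) and Neff columns are divided by 1000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ResidueProfile", "ProfileAlignmentError", "parse_pssm", "parse_hhm",
           "align_profile"]


class ProfileAlignmentError(ValueError):
    """Profile length does not match the target chain."""


@dataclass
class ResidueProfile:
    """Per-residue profile features in [0, 1].

    ``values`` is (n_residues, 20) for a PSSM or (n_residues, 30) for an HHM
    (20 match emissions + 7 transitions + 3 Neff columns); ``sequence`` is
    the one-letter sequence the profile was built from.
    """

    values: np.ndarray
    sequence: str
    kind: str  # "pssm" | "hhm"

    def __len__(self) -> int:
        return len(self.values)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def parse_pssm(text: str) -> ResidueProfile:
    """Parse a PSI-BLAST ascii PSSM (``-out_ascii_pssm``).

    Rows look like ``1 M  -2 -1 ... (20 log-odds) (20 pct) info weight``;
    the 20 log-odds columns are kept and logistic-squashed to (0, 1).
    """
    rows: list[list[float]] = []
    seq: list[str] = []
    for line in text.splitlines():
        parts = line.split()
        if len(parts) < 22:
            continue
        try:
            int(parts[0])
        except ValueError:
            continue
        if len(parts[1]) != 1 or not parts[1].isalpha():
            continue
        try:
            scores = [float(v) for v in parts[2:22]]
        except ValueError:
            continue
        rows.append(scores)
        seq.append(parts[1])
    if not rows:
        raise ValueError("no PSSM rows found")
    return ResidueProfile(_logistic(np.array(rows)), "".join(seq), "pssm")


def _decode_hhm(token: str) -> float:
    if token == "*":
        return 0.0
    return float(2.0 ** (-int(token) / 1000.0))


def parse_hhm(text: str) -> ResidueProfile:
    """Parse an HHblits ``.hhm`` profile.

    Each match state contributes 30 features: 20 match-emission
    probabilities, 7 transition probabilities, and 3 Neff values (scaled by
    1/1000).
    """
    lines = text.splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.startswith("HMM"))
    except StopIteration:
        raise ValueError("no HMM block found") from None
    i = start + 3  # skip the two header rows after "HMM"
    rows: list[list[float]] = []
    seq: list[str] = []
    while i + 1 < len(lines):
        em = lines[i].split()
        if not em or em[0] == "//":
            break
        if len(em) < 22:
            i += 1
            continue
        aa = em[0]
        emissions = [_decode_hhm(t) for t in em[2:22]]
        tr = lines[i + 1].split()
        if len(tr) < 10:
            raise ValueError(f"truncated transition line after residue {em[1]}")
        transitions = [_decode_hhm(t) for t in tr[:7]]
        neff = [int(t) / 1000.0 if t != "*" else 0.0 for t in tr[7:10]]
        rows.append(emissions + transitions + neff)
        seq.append(aa)
        i += 3  # emission line, transition line, blank line
    if not rows:
        raise ValueError("no HMM match states found")
    return ResidueProfile(np.array(rows), "".join(seq), "hhm")


def align_profile(profile: ResidueProfile, n_chain_residues: int) -> np.ndarray:
    """Check the profile covers the chain; returns the (n, k) value matrix.

    A length mismatch raises :class:`ProfileAlignmentError` reporting the
    offset at which coverage ends.
    """
    if len(profile) != n_chain_residues:
        raise ProfileAlignmentError(
            f"profile has {len(profile)} rows but chain has "
            f"{n_chain_residues} residues; coverage ends at offset "
            f"{min(len(profile), n_chain_residues)}"
        )
    return profile.values
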