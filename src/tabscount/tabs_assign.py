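"""Assign canonical TABS labels to conformers from 3D coordinates.

For each torsion bit the signed dihedral of its reference quadruple is
measured (IUPAC convention, degrees in (-180, 180]), binned by the bit's
pattern, and the resulting rawTABS is canonicalized under the molecule's
topological symmetry group.  Conformers related by a topological symmetry
of the molecule therefore receive the same TABS label.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from rdkit import Chem

from .bitstrings import RawTABS, TabsSystem, canonical_tabs
from .torsionlib import TorsionBit, assign_bin

__all__ = [
    "DegenerateGeometryError",
    "measure_dihedral",
    "assign_rawtabs",
    "assign_tabs",
    "conformer_coords",
    "label_ensemble",
]


class DegenerateGeometryError(ValueError):
    """Three of the four dihedral atoms are collinear: angle undefined."""


def measure_dihedral(
    coords: np.ndarray, quadruple: Sequence[int], tol: float = 1e-9
) -> float:
    """Signed dihedral a-b-c-d in degrees, normalized to (-180, 180].

    Sign follows the IUPAC convention: looking from b towards c, a
    positive angle turns a clockwise onto d.  Collinear triples make the
    torsion undefined and raise :class:`DegenerateGeometryError` — an
    arbitrary bin would silently corrupt the counts downstream.
    """
    coords = np.asarray(coords, dtype=float)
    a, b, c, d = (coords[i] for i in quadruple)
    b0 = b - a
    b1 = c - b
    b2 = d - c
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    scale = max(np.linalg.norm(v) for v in (b0, b1, b2))
    if (
        np.linalg.norm(n1) <= tol * scale**2
        or np.linalg.norm(n2) <= tol * scale**2
    ):
        raise DegenerateGeometryError(
            f"collinear atoms in quadruple {tuple(quadruple)}"
        )
    b1_hat = b1 / np.linalg.norm(b1)
    angle = float(
        np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b1_hat), np.dot(n1, n2)))
    )
    if angle <= -180.0:
        angle += 360.0
    return angle


def assign_rawtabs(coords: np.ndarray, bits: Sequence[TorsionBit]) -> RawTABS:
    """Bin every torsion of a conformer: the uncanonicalized bit string."""
    values = [0] * len(bits)
    for bit in bits:
        if bit.pattern is None:
            raise ValueError(
                f"bit {bit.bit_index} has no pattern; run assign_patterns first"
            )
        angle = measure_dihedral(coords, bit.quadruple)
        values[bit.bit_index] = assign_bin(angle, bit.pattern)
    return RawTABS(tuple(values))


def assign_tabs(
    coords: np.ndarray, bits: Sequence[TorsionBit], system: TabsSystem
) -> RawTABS:
    """Canonical TABS of a conformer (orbit representative of its rawTABS)."""
    raw = assign_rawtabs(coords, bits)
    system.validate(raw)
    return canonical_tabs(raw, system.group)


def conformer_coords(mol: Chem.Mol, conf_id: int = -1) -> np.ndarray:
    """(n_atoms, 3) coordinate array of one conformer, in Å."""
    return np.array(mol.GetConformer(conf_id).GetPositions(), dtype=float)


def label_ensemble(
    mol: Chem.Mol, bits: Sequence[TorsionBit], system: TabsSystem
) -> dict[str, str]:
    """TABS label (serialized) for every conformer of a multi-conformer Mol.

    Keys are conformer ids as strings, matching the pair-score tables
    consumed by the categorization framework.
    """
    labels = {}
    for conf in mol.GetConformers():
        coords = np.array(conf.GetPositions(), dtype=float)
        labels[str(conf.GetId())] = str(assign_tabs(coords, bits, system))
    return labels
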