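"""End-to-end molecule analysis: from a molecule to its TABS system.

Glue over the individual stages: rotatable-torsion perception and
pattern matching (`torsionlib`), symmetry projection (`symmetry`) and
exact state counting (`burnside`).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

from rdkit import Chem

from .bitstrings import TabsSystem, cardinality
from .burnside import SymmetryGroup, ntabs_burnside
from .categorize import flexibility_category
from .symmetry import build_group
from .torsionlib import (
    TorsionBit,
    TorsionPattern,
    assign_patterns,
    default_library,
    find_rotatable_torsions,
    mol_from_smiles,
)

__all__ = ["MoleculeTabs", "analyze_molecule"]


@dataclass(frozen=True)
class MoleculeTabs:
    """A molecule together with its torsion-bit layout and symmetry group."""

    mol: Chem.Mol
    bits: tuple[TorsionBit, ...]
    system: TabsSystem

    @property
    def n_bits(self) -> int:
        return self.system.n_bits

    @property
    def multiplicities(self) -> tuple[int, ...]:
        return self.system.multiplicities

    @property
    def group(self) -> SymmetryGroup:
        return self.system.group

    @cached_property
    def ntabs(self) -> int:
        """Exact number of distinct torsional states (Burnside count)."""
        return ntabs_burnside(self.system)

    @property
    def naive_state_count(self) -> int:
        """|S| = prod(m_i), ignoring symmetry."""
        return cardinality(self.system)

    @property
    def flexibility(self) -> str:
        return flexibility_category(self.ntabs)


def analyze_molecule(
    molecule: Chem.Mol | str,
    library: Sequence[TorsionPattern] | None = None,
) -> MoleculeTabs:
    """Build the full TABS description of a molecule.

    *molecule* may be an RDKit Mol or a SMILES string; *library*
    defaults to the curated library shipped with the package.
    """
    mol = mol_from_smiles(molecule) if isinstance(molecule, str) else molecule
    if library is None:
        library = default_library()
    bits = tuple(assign_patterns(find_rotatable_torsions(mol), library))
    group = build_group(mol, list(bits))
    system = TabsSystem(
        multiplicities=tuple(bit.multiplicity for bit in bits), group=group
    )
    return MoleculeTabs(mol=mol, bits=bits, system=system)
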