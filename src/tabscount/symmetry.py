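"""Topological symmetry: graph automorphisms and their action on TABS bits.

A topological symmetry is a permutation of the atom numbering that leaves
atom types and connectivity unchanged — an automorphism of the labeled
molecular graph.  Each such automorphism maps rotatable bonds onto
rotatable bonds and therefore induces a permutation of the TABS bits.
The image of the atom automorphism group under this projection is the
group G used by Burnside counting; several atom permutations may project
to the same bit permutation (e.g. a phenyl ring flip that fixes every
torsion bond), so the image is deduplicated.

Automorphisms are enumerated on the heavy-atom graph: hydrogens permute
only within their parent atom's coordination sphere and can never move a
torsion bond, so they are irrelevant to the bit action.  Atom "type"
resolution is element + formal charge + aromaticity; bonds compare by
order + aromaticity.  Stereochemistry is deliberately ignored — the
symmetry is graph-topological, so enantiomeric torsion states merge.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
from networkx.algorithms import isomorphism
from rdkit import Chem

from .burnside import BitPermutation, SymmetryGroup
from .torsionlib import TorsionBit

__all__ = [
    "AtomPermutation",
    "AutomorphismCapExceeded",
    "ProjectionError",
    "atom_automorphisms",
    "project_to_bits",
    "build_group",
]

#: default cap on the atom automorphism group order
DEFAULT_AUTOMORPHISM_CAP = 10**5


class AutomorphismCapExceeded(RuntimeError):
    """The automorphism group is larger than the configured cap."""


class ProjectionError(ValueError):
    """An automorphism is inconsistent with the torsion-bit layout."""


@dataclass(frozen=True)
class AtomPermutation:
    """A bijection on (heavy) atom indices, stored as sorted (i, σ(i)) pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple(sorted((int(a), int(b)) for a, b in self.pairs))
        object.__setattr__(self, "pairs", pairs)
        src = [a for a, _ in pairs]
        dst = sorted(b for _, b in pairs)
        if src != dst or len(set(src)) != len(src):
            raise ValueError("not a bijection on its own index set")

    @classmethod
    def from_dict(cls, mapping: dict[int, int]) -> "AtomPermutation":
        return cls(tuple(mapping.items()))

    def __getitem__(self, atom_idx: int) -> int:
        return dict(self.pairs)[atom_idx]

    def as_dict(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def is_identity(self) -> bool:
        return all(a == b for a, b in self.pairs)

    def compose(self, other: "AtomPermutation") -> "AtomPermutation":
        """``self ∘ other``: apply *other* first."""
        o = other.as_dict()
        s = self.as_dict()
        return AtomPermutation.from_dict({i: s[j] for i, j in o.items()})


def _heavy_atom_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() > 1:
            g.add_node(
                atom.GetIdx(),
                kind=(
                    atom.GetAtomicNum(),
                    atom.GetFormalCharge(),
                    atom.GetIsAromatic(),
                ),
            )
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in g and j in g:
            g.add_edge(i, j, kind=(bond.GetBondTypeAsDouble(), bond.GetIsAromatic()))
    return g


def atom_automorphisms(
    mol: Chem.Mol, max_order: int = DEFAULT_AUTOMORPHISM_CAP
) -> frozenset[AtomPermutation]:
    """Full automorphism group of the labeled heavy-atom graph.

    Backtracking (VF2) search with atoms constrained to map within their
    (element, charge, aromaticity) class and bonds within their
    (order, aromaticity) class.  Raises
    :class:`AutomorphismCapExceeded` beyond *max_order* rather than
    silently truncating the group.
    """
    graph = _heavy_atom_graph(mol)
    if graph.number_of_nodes() == 0:
        return frozenset({AtomPermutation(())})
    matcher = isomorphism.GraphMatcher(
        graph,
        graph,
        node_match=isomorphism.categorical_node_match("kind", None),
        edge_match=isomorphism.categorical_edge_match("kind", None),
    )
    perms = [
        AtomPermutation.from_dict(m)
        for m in itertools.islice(matcher.isomorphisms_iter(), max_order + 1)
    ]
    if len(perms) > max_order:
        raise AutomorphismCapExceeded(
            f"automorphism group exceeds cap {max_order}"
        )
    return frozenset(perms)


def project_to_bits(
    atom_perm: AtomPermutation, bits: list[TorsionBit]
) -> BitPermutation:
    """Bit permutation induced by an atom automorphism.

    Bond {b, c} maps to bond {σ(b), σ(c)}; each torsion bond must land on
    a torsion bond of identical multiplicity — a violation signals an
    inconsistency between the symmetry and the pattern matching and is a
    hard error, because it would corrupt fixpoint counting.
    """
    bond_to_bit = {frozenset(bit.bond): bit.bit_index for bit in bits}
    sigma = atom_perm.as_dict()
    mapping = [0] * len(bits)
    for bit in bits:
        b, c = bit.bond
        image = frozenset((sigma[b], sigma[c]))
        target = bond_to_bit.get(image)
        if target is None:
            raise ProjectionError(
                f"automorphism maps torsion bond {bit.bond} to non-torsion "
                f"bond {tuple(sorted(image))}"
            )
        if (
            bit.multiplicity is not None
            and bits[target].multiplicity != bit.multiplicity
        ):
            raise ProjectionError(
                f"automorphism maps bit {bit.bit_index} (m={bit.multiplicity}) "
                f"to bit {target} (m={bits[target].multiplicity})"
            )
        mapping[bit.bit_index] = target
    return BitPermutation(tuple(mapping))


def build_group(
    mol: Chem.Mol,
    bits: list[TorsionBit],
    max_atom_order: int = DEFAULT_AUTOMORPHISM_CAP,
) -> SymmetryGroup:
    """The bit-permutation group G: project, deduplicate, verify.

    Distinct atom automorphisms frequently induce the same bit
    permutation; Burnside's lemma is applied to the group actually
    acting on the strings, so duplicates are removed and |G| is the
    order of the image group.  Closure and identity membership are
    re-verified after deduplication.
    """
    autos = atom_automorphisms(mol, max_order=max_atom_order)
    image = {project_to_bits(a, bits) for a in autos}
    return SymmetryGroup(image)
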