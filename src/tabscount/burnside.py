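"""Exact counting of TABS via Burnside's lemma.

The number of distinct TABS (orbits of rawTABS under the bit-permutation
symmetry group G) is

    nTABS = |T| = (1/|G|) * sum_{g in G} |Fix(g)|,

the Cauchy-Frobenius / Burnside orbit-counting lemma.  |Fix(g)| is cheap:
a rawTABS is fixed by g iff it is constant on every cycle of g, so
|Fix(g)| is the product over cycles of the (common) multiplicity of the
bits in that cycle.  The whole computation costs O(|G| * N) — it never
touches the exponentially large set S.  The naive enumerate-and-
deduplicate path is kept as a brute-force oracle for cross-validation.

All arithmetic is exact arbitrary-precision integer arithmetic; nTABS for
flexible molecules is routinely astronomically large.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = [
    "BitPermutation",
    "SymmetryGroup",
    "MultiplicityMismatchError",
    "GroupClosureError",
    "fixpoint_count",
    "ntabs_burnside",
    "ntabs_naive",
    "stabilizer",
]

#: default bound on the order of a group built by closure of generators
DEFAULT_GROUP_CAP = 10**6


class MultiplicityMismatchError(ValueError):
    """A permutation cycle spans bits of unequal multiplicity."""


class GroupClosureError(ValueError):
    """A set of permutations is not (or cannot be verified to be) a group."""


@dataclass(frozen=True)
class BitPermutation:
    """A bijection on bit positions ``{1..N}`` (stored 0-based).

    ``mapping[i]`` is the (0-based) image of bit i.  Bit permutations
    arising from molecular topological symmetry only ever exchange bits
    of identical multiplicity; that constraint is enforced where the
    multiplicities are known (`TabsSystem`, `fixpoint_count`), not here.
    """

    mapping: tuple[int, ...]

    def __post_init__(self) -> None:
        mapping = tuple(int(i) for i in self.mapping)
        object.__setattr__(self, "mapping", mapping)
        if sorted(mapping) != list(range(len(mapping))):
            raise ValueError(f"not a bijection on 0..{len(mapping) - 1}: {mapping}")

    @classmethod
    def identity(cls, n: int) -> "BitPermutation":
        return cls(tuple(range(n)))

    @classmethod
    def from_cycles(cls, n: int, *cycles: Iterable[int]) -> "BitPermutation":
        """Build from disjoint cycles of 1-based bit indices.

        ``from_cycles(3, (1, 2, 3))`` maps bit 1 -> 2 -> 3 -> 1.
        """
        mapping = list(range(n))
        for cycle in cycles:
            cyc = [c - 1 for c in cycle]
            for a, b in zip(cyc, cyc[1:] + cyc[:1]):
                mapping[a] = b
        return cls(tuple(mapping))

    @property
    def degree(self) -> int:
        return len(self.mapping)

    @property
    def is_identity(self) -> bool:
        return all(j == i for i, j in enumerate(self.mapping))

    def __call__(self, i: int) -> int:
        """Image of 1-based bit index i, 1-based."""
        return self.mapping[i - 1] + 1

    def compose(self, other: "BitPermutation") -> "BitPermutation":
        """``self ∘ other``: apply *other* first, then *self*."""
        if self.degree != other.degree:
            raise ValueError("cannot compose permutations of different degree")
        return BitPermutation(tuple(self.mapping[j] for j in other.mapping))

    def inverse(self) -> "BitPermutation":
        inv = [0] * self.degree
        for i, j in enumerate(self.mapping):
            inv[j] = i
        return BitPermutation(tuple(inv))

    def cycles(self) -> list[tuple[int, ...]]:
        """Cycle decomposition as 0-based index tuples (fixed points included)."""
        seen = [False] * self.degree
        out: list[tuple[int, ...]] = []
        for start in range(self.degree):
            if seen[start]:
                continue
            cyc = [start]
            seen[start] = True
            j = self.mapping[start]
            while j != start:
                seen[j] = True
                cyc.append(j)
                j = self.mapping[j]
            out.append(tuple(cyc))
        return out

    def __str__(self) -> str:
        cycs = [c for c in self.cycles() if len(c) > 1]
        if not cycs:
            return "I"
        return "".join("(" + " ".join(str(i + 1) for i in c) + ")" for c in cycs)


class SymmetryGroup:
    """A finite group of bit permutations (the paper-level symbol G).

    Construction verifies the group axioms that matter for Burnside:
    presence of the identity and closure under composition (inverses
    follow from finiteness but are checked too).  Use
    :meth:`from_generators` to build the closure of an arbitrary
    generating set.
    """

    def __init__(self, elements: Iterable[BitPermutation]):
        elems = frozenset(elements)
        if not elems:
            raise GroupClosureError("a group cannot be empty")
        degrees = {g.degree for g in elems}
        if len(degrees) != 1:
            raise GroupClosureError(f"mixed permutation degrees: {degrees}")
        self._degree = degrees.pop()
        if BitPermutation.identity(self._degree) not in elems:
            raise GroupClosureError("group does not contain the identity")
        for g in elems:
            if g.inverse() not in elems:
                raise GroupClosureError(f"group not closed under inversion at {g}")
        for g, h in itertools.product(elems, repeat=2):
            if g.compose(h) not in elems:
                raise GroupClosureError(
                    f"group not closed under composition at {g} * {h}"
                )
        # stable iteration order for deterministic canonical forms
        self._elements = tuple(sorted(elems, key=lambda g: g.mapping))

    @classmethod
    def trivial(cls, n: int) -> "SymmetryGroup":
        return cls((BitPermutation.identity(n),))

    @classmethod
    def from_generators(
        cls,
        generators: Iterable[BitPermutation],
        degree: int | None = None,
        max_order: int = DEFAULT_GROUP_CAP,
    ) -> "SymmetryGroup":
        """Closure of *generators* under composition (plus the identity).

        A non-closed element set would silently break Burnside's lemma,
        so closure is always taken; *max_order* bounds the work.
        """
        gens = list(generators)
        if degree is None:
            if not gens:
                raise ValueError("degree required when no generators are given")
            degree = gens[0].degree
        identity = BitPermutation.identity(degree)
        elements = {identity}
        frontier = [identity]
        while frontier:
            nxt = []
            for g in frontier:
                for h in gens:
                    prod = h.compose(g)
                    if prod not in elements:
                        elements.add(prod)
                        nxt.append(prod)
                        if len(elements) > max_order:
                            raise GroupClosureError(
                                f"group closure exceeds cap {max_order}"
                            )
            frontier = nxt
        return cls(elements)

    @property
    def degree(self) -> int:
        return self._degree

    @property
    def order(self) -> int:
        return len(self._elements)

    def __len__(self) -> int:
        return len(self._elements)

    def __iter__(self) -> Iterator[BitPermutation]:
        return iter(self._elements)

    def __contains__(self, g: BitPermutation) -> bool:
        return g in set(self._elements)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SymmetryGroup):
            return NotImplemented
        return self._elements == other._elements

    def __hash__(self) -> int:
        return hash(self._elements)

    def __repr__(self) -> str:
        return f"SymmetryGroup(order={self.order}, degree={self.degree})"


def fixpoint_count(g: BitPermutation, multiplicities: tuple[int, ...]) -> int:
    """|Fix(g)|: number of rawTABS left invariant by *g*, in O(N).

    A string is fixed by g iff it is constant on every cycle of g, so the
    count is the product over cycles of the common multiplicity of the
    bits in the cycle.
    """
    if g.degree != len(multiplicities):
        raise ValueError(
            f"permutation degree {g.degree} != N = {len(multiplicities)}"
        )
    total = 1
    for cycle in g.cycles():
        m = multiplicities[cycle[0]]
        for i in cycle[1:]:
            if multiplicities[i] != m:
                raise MultiplicityMismatchError(
                    f"cycle {tuple(i + 1 for i in cycle)} spans multiplicities "
                    f"{sorted({multiplicities[i] for i in cycle})}"
                )
        total *= m
    return total


def ntabs_burnside(system) -> int:
    """Exact nTABS = (1/|G|) * sum_{g in G} |Fix(g)|.

    Burnside's lemma guarantees the division is exact for a genuine
    group; a nonzero remainder signals a corrupted (non-closed) group
    and raises :class:`GroupClosureError`.
    """
    group = system.group
    mults = system.multiplicities
    # module-level lookup is deliberate: tests instrument fixpoint_count
    total = sum(fixpoint_count(g, mults) for g in group)
    orbits, remainder = divmod(total, group.order)
    if remainder:
        raise GroupClosureError(
            f"Burnside sum {total} not divisible by |G| = {group.order}; "
            "the supplied element set is not a group"
        )
    return orbits


def ntabs_naive(system, cap: int | None = None) -> int:
    """Brute-force nTABS oracle: enumerate S, canonicalize, deduplicate.

    Cost is O(|G| * M); use only on small systems (*cap* limits M).
    """
    from .bitstrings import DEFAULT_ENUMERATION_CAP, _act, cardinality

    if cap is None:
        cap = DEFAULT_ENUMERATION_CAP
    m = cardinality(system)
    if m > cap:
        from .bitstrings import EnumerationCapExceeded

        raise EnumerationCapExceeded(f"|S| = {m} exceeds cap {cap}")
    # count orbit representatives: a string is counted iff no group
    # element produces a lexicographically smaller image (early exit)
    mappings = [g.mapping for g in system.group if not g.is_identity]
    count = 0
    for values in itertools.product(
        *(range(1, mi + 1) for mi in system.multiplicities)
    ):
        if all(_act(values, mapping) >= values for mapping in mappings):
            count += 1
    return count


def stabilizer(s, group: SymmetryGroup) -> frozenset[BitPermutation]:
    """Stab(s) = {g in G : g·s = s}; always contains the identity.

    By the orbit-stabilizer theorem |Orb(s)| * |Stab(s)| = |G|.
    """
    from .bitstrings import apply_permutation

    return frozenset(g for g in group if apply_permutation(s, g) == s)
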