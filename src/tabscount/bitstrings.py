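"""Multi-radix bit strings (rawTABS) and the set S they live in.

A rawTABS is a string of N integer "bits"; bit i takes values in
``[1, m_i]`` where ``m_i`` is the multiplicity of torsion i.  The full set
S of rawTABS has cardinality ``M = prod(m_i)``.  A molecule's topological
symmetry group acts on S by permuting bits; a TABS is the lexicographically
smallest member of an orbit under that action.

This module is chemistry-free: it knows nothing about molecules, only
about bit strings, multiplicities and permutations of bit positions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "RawTABS",
    "TabsSystem",
    "DimensionMismatchError",
    "EnumerationCapExceeded",
    "cardinality",
    "enumerate_rawtabs",
    "apply_permutation",
    "canonical_tabs",
    "orbit",
]

#: default safety cap for exhaustive enumeration of S
DEFAULT_ENUMERATION_CAP = 10**7


class DimensionMismatchError(ValueError):
    """Raised when a rawTABS, permutation or system disagree on N."""


class EnumerationCapExceeded(RuntimeError):
    """Raised when |S| exceeds the safety cap for exhaustive enumeration."""


@dataclass(frozen=True, order=True)
class RawTABS:
    """An uncanonicalized torsion bin string: one 1-based value per bit.

    Ordering is lexicographic on the values, which is exactly the order
    used to pick canonical orbit representatives.
    """

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = tuple(int(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if any(v < 1 for v in vals):
            raise ValueError(f"bit values must be >= 1, got {vals}")

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[int]:
        return iter(self.values)

    def __str__(self) -> str:
        return "-".join(str(v) for v in self.values) if self.values else "-"

    @classmethod
    def from_string(cls, text: str) -> "RawTABS":
        """Parse the hyphen-separated serialization, e.g. ``"1-3-2"``."""
        text = text.strip()
        if text in ("", "-"):
            return cls(())
        return cls(tuple(int(tok) for tok in text.split("-")))


@dataclass(frozen=True)
class TabsSystem:
    """Abstract description of a molecule's torsion bits.

    Parameters
    ----------
    multiplicities
        Number of angular bins of each bit, ``m_1 .. m_N``.
    group
        The bit-permutation symmetry group acting on the strings.  If
        omitted, the trivial group is used.  Every group element must
        permute bits only within identical multiplicities.
    """

    multiplicities: tuple[int, ...]
    group: "SymmetryGroup" = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        from .burnside import SymmetryGroup  # deferred: sibling module

        mults = tuple(int(m) for m in self.multiplicities)
        object.__setattr__(self, "multiplicities", mults)
        if any(m < 1 for m in mults):
            raise ValueError(f"multiplicities must be positive, got {mults}")
        group = self.group
        if group is None:
            group = SymmetryGroup.trivial(len(mults))
        object.__setattr__(self, "group", group)
        if group.degree != len(mults):
            raise DimensionMismatchError(
                f"group degree {group.degree} != N = {len(mults)}"
            )
        for g in group:
            for i, j in enumerate(g.mapping):
                if mults[i] != mults[j]:
                    raise ValueError(
                        "group permutes bits of unequal multiplicity: "
                        f"bit {i + 1} (m={mults[i]}) -> bit {j + 1} (m={mults[j]})"
                    )

    @property
    def n_bits(self) -> int:
        return len(self.multiplicities)

    def validate(self, s: RawTABS) -> None:
        """Check that *s* is a member of this system's set S."""
        if len(s) != self.n_bits:
            raise DimensionMismatchError(
                f"rawTABS has {len(s)} bits, system has {self.n_bits}"
            )
        for i, (v, m) in enumerate(zip(s.values, self.multiplicities)):
            if not 1 <= v <= m:
                raise ValueError(
                    f"bit {i + 1} value {v} outside [1, {m}]"
                )


def cardinality(system: TabsSystem) -> int:
    """Size of the rawTABS set, ``M = |S| = prod(m_i)`` (exact integer).

    The empty system (N = 0) has exactly one (empty) string, so M = 1.
    """
    return math.prod(system.multiplicities)


def enumerate_rawtabs(
    system: TabsSystem, cap: int = DEFAULT_ENUMERATION_CAP
) -> Iterator[RawTABS]:
    """Yield every element of S exactly once, in lexicographic order.

    Exhaustive enumeration is a test/oracle tool, not a production path:
    M grows exponentially with N, hence the mandatory safety *cap*.
    """
    m = cardinality(system)
    if m > cap:
        raise EnumerationCapExceeded(f"|S| = {m} exceeds cap {cap}")
    for values in itertools.product(
        *(range(1, mi + 1) for mi in system.multiplicities)
    ):
        yield RawTABS(values)


def _act(values: tuple[int, ...], mapping: tuple[int, ...]) -> tuple[int, ...]:
    """Tuple-level left action (fast path shared by the oracle loops)."""
    out = [0] * len(mapping)
    for i, j in enumerate(mapping):
        out[j] = values[i]
    return tuple(out)


def apply_permutation(s: RawTABS, g: "BitPermutation") -> RawTABS:
    """Act with bit permutation *g* on *s* (left action).

    The value of bit i moves to position g(i):  ``(g·s)[g(i)] = s[i]``.
    """
    if len(s) != g.degree:
        raise DimensionMismatchError(
            f"rawTABS has {len(s)} bits, permutation degree {g.degree}"
        )
    return RawTABS(_act(s.values, g.mapping))


def canonical_tabs(s: RawTABS, group: "SymmetryGroup") -> RawTABS:
    """Lexicographically smallest member of the orbit of *s* — the TABS.

    This is a class function: every member of an orbit maps to the same
    canonical representative, so two rawTABS have equal canonical forms
    iff they lie in the same orbit.
    """
    return min(apply_permutation(s, g) for g in group)


def orbit(s: RawTABS, group: "SymmetryGroup") -> frozenset[RawTABS]:
    """Orb(s) = {g·s : g in group}.  Its size divides |group|."""
    return frozenset(apply_permutation(s, g) for g in group)


# imported late to avoid a cycle at module load; used in annotations only
from .burnside import BitPermutation, SymmetryGroup  # noqa: E402
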