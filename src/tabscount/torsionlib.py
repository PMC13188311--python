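"""Torsion-pattern library and matching of rotatable torsions to patterns.

Each rotatable bond of a molecule becomes one bit of the TABS string; the
torsion pattern matched to the bond supplies the bit's multiplicity (its
number of angular bins).  The package ships a small curated library
(``data/torsion_library.yaml``); user libraries in the same YAML format —
for instance the full CSD-derived library — can be dropped in.

Conventions (fixed so that results are reproducible):

* dihedral angles in degrees, IUPAC sign convention, normalized to
  ``(-180, 180]``;
* bins half-open ``(lower, upper]``, wrapping across ±180°;
* a bond is rotatable iff it is a non-ring single bond between two heavy
  atoms, each of which has at least one heavy neighbor besides the other;
* bits are ordered by the canonical atom ranks of their bond atoms;
* the reference quadruple (a, b, c, d) uses, on each side, the heavy
  neighbor with the smallest canonical rank (ties broken by atom index).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import yaml
from rdkit import Chem

__all__ = [
    "TorsionPattern",
    "TorsionBit",
    "LibraryError",
    "NoMatchError",
    "load_library",
    "default_library",
    "find_rotatable_torsions",
    "match_pattern",
    "assign_patterns",
    "assign_bin",
    "is_rotatable",
    "mol_from_smiles",
    "read_molecules",
]


class LibraryError(ValueError):
    """Invalid torsion-pattern library."""


class NoMatchError(LookupError):
    """No pattern in the library matches a torsion bond."""


@dataclass(frozen=True)
class TorsionPattern:
    """A substructure pattern with angular bin definitions.

    ``smarts`` must carry four mapped atoms; atoms ``:2``/``:3`` are the
    bond atoms.  ``boundaries`` are the bin edges (degrees, strictly
    increasing, within (-180, 180]); their count is the multiplicity.
    Lower ``priority`` = more specific = matched first.
    """

    pattern_id: str
    smarts: str
    boundaries: tuple[float, ...]
    priority: int
    query: Chem.Mol = field(compare=False, repr=False, default=None)  # type: ignore

    def __post_init__(self) -> None:
        bounds = tuple(float(b) for b in self.boundaries)
        object.__setattr__(self, "boundaries", bounds)
        if not bounds:
            raise LibraryError(f"{self.pattern_id}: no bin boundaries")
        if any(not (-180.0 < b <= 180.0) for b in bounds):
            raise LibraryError(
                f"{self.pattern_id}: boundaries must lie in (-180, 180]: {bounds}"
            )
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise LibraryError(
                f"{self.pattern_id}: boundaries not strictly increasing: {bounds}"
            )
        query = Chem.MolFromSmarts(self.smarts)
        if query is None:
            raise LibraryError(f"{self.pattern_id}: invalid SMARTS {self.smarts!r}")
        maps = sorted(a.GetAtomMapNum() for a in query.GetAtoms() if a.GetAtomMapNum())
        if maps != [1, 2, 3, 4]:
            raise LibraryError(
                f"{self.pattern_id}: SMARTS must map exactly atoms 1..4, got {maps}"
            )
        object.__setattr__(self, "query", query)

    @property
    def multiplicity(self) -> int:
        """Number of angular bins on the circle."""
        return len(self.boundaries)

    def bond_query_atoms(self) -> tuple[int, int]:
        """Query-atom indices carrying map numbers 2 and 3."""
        pos = {a.GetAtomMapNum(): a.GetIdx() for a in self.query.GetAtoms()}
        return pos[2], pos[3]

    def bin_arcs(self) -> list[float]:
        """Arc length of each bin in degrees (sums to 360)."""
        b = self.boundaries
        arcs = [b[0] - (b[-1] - 360.0)]
        arcs.extend(b[i] - b[i - 1] for i in range(1, len(b)))
        return arcs


@dataclass(frozen=True)
class TorsionBit:
    """One matched rotatable torsion of a concrete molecule.

    ``bond`` is the unordered pair of bond atom indices; ``quadruple``
    the ordered reference atoms (a, b, c, d) used to measure the
    dihedral; ``bit_index`` the 0-based position in the TABS string.
    """

    bond: tuple[int, int]
    quadruple: tuple[int, int, int, int]
    pattern_id: str | None = None
    multiplicity: int | None = None
    bit_index: int = -1
    mol: Chem.Mol = field(compare=False, repr=False, default=None)  # type: ignore
    pattern: TorsionPattern | None = field(compare=False, repr=False, default=None)


def load_library(path: str | Path) -> list[TorsionPattern]:
    """Load and validate a torsion-pattern library from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _parse_library(raw, source=str(path))


def default_library() -> list[TorsionPattern]:
    """The curated library shipped with the package."""
    text = (
        resources.files("tabscount") / "data" / "torsion_library.yaml"
    ).read_text()
    return _parse_library(yaml.safe_load(text), source="<builtin>")


def _parse_library(raw: object, source: str) -> list[TorsionPattern]:
    if not isinstance(raw, dict) or "patterns" not in raw:
        raise LibraryError(f"{source}: expected a mapping with a 'patterns' list")
    entries = raw["patterns"]
    if not entries:
        raise LibraryError(f"{source}: empty pattern list")
    patterns = []
    seen: set[str] = set()
    for rank, entry in enumerate(entries):
        pid = str(entry["id"])
        if pid in seen:
            raise LibraryError(f"{source}: duplicate pattern id {pid!r}")
        seen.add(pid)
        patterns.append(
            TorsionPattern(
                pattern_id=pid,
                smarts=str(entry["smarts"]),
                boundaries=tuple(entry["boundaries"]),
                priority=rank,
            )
        )
    return patterns


def is_rotatable(bond: Chem.Bond) -> bool:
    """Rotatability rule for TABS bits.

    A non-ring single bond between heavy atoms, where each bond atom has
    at least one heavy (non-hydrogen) neighbor besides the other.
    """
    if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
        return False
    a, b = bond.GetBeginAtom(), bond.GetEndAtom()
    if a.GetAtomicNum() <= 1 or b.GetAtomicNum() <= 1:
        return False

    def has_heavy_neighbor(atom: Chem.Atom, exclude: int) -> bool:
        return any(
            nbr.GetAtomicNum() > 1 and nbr.GetIdx() != exclude
            for nbr in atom.GetNeighbors()
        )

    return has_heavy_neighbor(a, b.GetIdx()) and has_heavy_neighbor(b, a.GetIdx())


def find_rotatable_torsions(mol: Chem.Mol) -> list[TorsionBit]:
    """One TorsionBit per rotatable bond, in canonical order.

    Bits are sorted by the pair of canonical atom ranks of the bond
    atoms (ties by atom indices), so the layout is stable under atom
    relabeling up to symmetry-equivalent bonds.  Patterns are not yet
    assigned; see :func:`assign_patterns`.
    """
    ranks = list(Chem.CanonicalRankAtoms(mol, breakTies=False))
    bits = []
    for bond in mol.GetBonds():
        if not is_rotatable(bond):
            continue
        b, c = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        # orient the bond so that the lower-ranked atom comes first
        if (ranks[b], b) > (ranks[c], c):
            b, c = c, b
        a = _reference_neighbor(mol, ranks, b, exclude=c)
        d = _reference_neighbor(mol, ranks, c, exclude=b)
        bits.append(
            TorsionBit(
                bond=(min(b, c), max(b, c)), quadruple=(a, b, c, d), mol=mol
            )
        )
    bits.sort(
        key=lambda t: (
            tuple(sorted((ranks[t.bond[0]], ranks[t.bond[1]]))),
            t.bond,
        )
    )
    return [
        TorsionBit(
            bond=t.bond, quadruple=t.quadruple, bit_index=i, mol=t.mol
        )
        for i, t in enumerate(bits)
    ]


def _reference_neighbor(
    mol: Chem.Mol, ranks: Sequence[int], atom_idx: int, exclude: int
) -> int:
    """Heavy neighbor with smallest canonical rank (tie: smallest index)."""
    candidates = [
        nbr.GetIdx()
        for nbr in mol.GetAtomWithIdx(atom_idx).GetNeighbors()
        if nbr.GetIdx() != exclude and nbr.GetAtomicNum() > 1
    ]
    if not candidates:
        raise ValueError(
            f"atom {atom_idx} has no heavy neighbor besides {exclude}; "
            "bond should not have qualified as rotatable"
        )
    return min(candidates, key=lambda i: (ranks[i], i))


def match_pattern(
    bit: TorsionBit, library: Sequence[TorsionPattern]
) -> TorsionPattern:
    """First (highest-priority) pattern whose bond atoms match the bit's bond.

    The library is scanned in priority order; a match requires the
    pattern's mapped atoms :2/:3 to coincide with the bond atoms (either
    orientation).  A well-formed library ends with a catch-all, so a
    NoMatchError indicates the catch-all was removed.
    """
    if bit.mol is None:
        raise ValueError("TorsionBit carries no molecule reference")
    bond_set = set(bit.bond)
    for pattern in sorted(library, key=lambda p: p.priority):
        q2, q3 = pattern.bond_query_atoms()
        for match in bit.mol.GetSubstructMatches(
            pattern.query, uniquify=False, maxMatches=10000
        ):
            if {match[q2], match[q3]} == bond_set:
                return pattern
    raise NoMatchError(
        f"no pattern matches bond {bit.bond}; library lacks a catch-all"
    )


def assign_patterns(
    bits: Sequence[TorsionBit], library: Sequence[TorsionPattern]
) -> list[TorsionBit]:
    """Return bits with pattern id and multiplicity filled in."""
    out = []
    for bit in bits:
        pattern = match_pattern(bit, library)
        out.append(
            TorsionBit(
                bond=bit.bond,
                quadruple=bit.quadruple,
                pattern_id=pattern.pattern_id,
                multiplicity=pattern.multiplicity,
                bit_index=bit.bit_index,
                mol=bit.mol,
                pattern=pattern,
            )
        )
    return out


def assign_bin(angle: float, pattern: TorsionPattern) -> int:
    """Angular bin (1-based) of a normalized dihedral under *pattern*.

    With edges ``b_1 < ... < b_k``, bin 1 is the wrap-around arc
    ``(b_k - 360, b_1]`` and bin i is ``(b_{i-1}, b_i]``.  Half-open
    bins make boundary angles deterministic.
    """
    if not (-180.0 < angle <= 180.0):
        raise ValueError(f"angle {angle} not normalized to (-180, 180]")
    i = bisect_left(pattern.boundaries, angle)
    return 1 if i == len(pattern.boundaries) else i + 1


# ---------------------------------------------------------------------------
# molecule input

def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    return mol


def read_molecules(path: str | Path) -> list[tuple[str, Chem.Mol]]:
    """Read (name, molecule) pairs from a .smi or .sdf file.

    SMILES files hold one molecule per line (``SMILES [id]``); SDF files
    may hold multiple records (multi-conformer handling is elsewhere).
    """
    path = Path(path)
    out: list[tuple[str, Chem.Mol]] = []
    if path.suffix.lower() in (".smi", ".smiles", ".txt"):
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fieldsplit = line.split(None, 1)
            smiles = fieldsplit[0]
            name = fieldsplit[1].strip() if len(fieldsplit) > 1 else f"mol{lineno}"
            out.append((name, mol_from_smiles(smiles)))
    elif path.suffix.lower() == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                raise ValueError(f"unparseable record {i} in {path}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}"
            out.append((name or f"mol{i + 1}", mol))
    else:
        raise ValueError(f"unsupported molecule file type: {path.suffix}")
    return out
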