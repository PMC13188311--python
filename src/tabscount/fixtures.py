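"""Synthetic inputs: random bit-systems, molecule fixtures, ensembles.

Everything here is generated, seeded and chemistry-light so the whole
package is testable without external data:

* :func:`random_system` draws abstract TABS systems (bit counts,
  multiplicities, a symmetry group generated by random
  multiplicity-respecting permutations) for the Burnside-vs-naive
  oracle battery;
* :func:`molecule_fixtures` ships a handful of hard-coded small
  molecules with hand-derived expectations;
* :func:`synthetic_ensemble` emulates the label-level statistical
  structure of a conformer ensemble: TABS labels sampled uniformly from
  S plus pairwise metric scores drawn from one distribution for
  equal-TABS pairs and another for unequal pairs.  No 3D geometry is
  generated — these ensembles exercise the categorization framework,
  not the conformer labeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .bitstrings import RawTABS, TabsSystem, canonical_tabs
from .burnside import BitPermutation, SymmetryGroup
from .categorize import PairScore

__all__ = [
    "SystemSpec",
    "random_system",
    "random_rawtabs",
    "fig2_system",
    "MoleculeFixture",
    "molecule_fixtures",
    "synthetic_ensemble",
]


@dataclass(frozen=True)
class SystemSpec:
    """Ranges for random system generation (all bounds inclusive)."""

    n_bits_min: int = 1
    n_bits_max: int = 6
    mult_min: int = 1
    mult_max: int = 4
    n_generators: int = 2
    max_group_order: int = 10**4

    def __post_init__(self) -> None:
        if self.n_bits_min < 0 or self.n_bits_max < self.n_bits_min:
            raise ValueError("empty n_bits range")
        if self.mult_min < 1 or self.mult_max < self.mult_min:
            raise ValueError("empty multiplicity range")
        if self.n_generators < 0:
            raise ValueError("negative generator count")


def _random_class_permutation(
    multiplicities: tuple[int, ...], rng: np.random.Generator
) -> BitPermutation:
    """A random permutation moving bits only within equal-multiplicity classes."""
    n = len(multiplicities)
    classes: dict[int, list[int]] = {}
    for i, m in enumerate(multiplicities):
        classes.setdefault(m, []).append(i)
    mapping = [0] * n
    for members in classes.values():
        images = list(members)
        rng.shuffle(images)
        for src, dst in zip(members, images):
            mapping[src] = dst
    return BitPermutation(tuple(mapping))


def random_system(
    spec: SystemSpec = SystemSpec(),
    seed: int | np.random.Generator = 0,
) -> TabsSystem:
    """Draw a random TabsSystem; deterministic for a given seed.

    The group is the closure of ``spec.n_generators`` random
    multiplicity-respecting permutations (plus the identity), so it is a
    genuine group by construction.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = int(rng.integers(spec.n_bits_min, spec.n_bits_max + 1))
    mults = tuple(
        int(rng.integers(spec.mult_min, spec.mult_max + 1)) for _ in range(n)
    )
    generators = [
        _random_class_permutation(mults, rng) for _ in range(spec.n_generators)
    ]
    group = SymmetryGroup.from_generators(
        generators, degree=n, max_order=spec.max_group_order
    )
    return TabsSystem(multiplicities=mults, group=group)


def random_rawtabs(system: TabsSystem, rng: np.random.Generator) -> RawTABS:
    """One rawTABS sampled uniformly from S."""
    return RawTABS(
        tuple(int(rng.integers(1, m + 1)) for m in system.multiplicities)
    )


def fig2_system() -> TabsSystem:
    """The two-equivalent-torsions textbook system: N=2, m=(3,3), G={I, swap}.

    |S| = 9 rawTABS; the swap identifies mirror-image strings, leaving 6
    distinct TABS (unordered pairs with repetition from 3 values).
    """
    swap = BitPermutation.from_cycles(2, (1, 2))
    return TabsSystem(
        multiplicities=(3, 3), group=SymmetryGroup.from_generators([swap])
    )


@dataclass(frozen=True)
class MoleculeFixture:
    """A hard-coded molecule with hand-derived TABS expectations.

    ``n_bits``/``group_order`` refer to the torsion-bit layout and the
    projected bit-permutation group under the shipped default library;
    both were derived by hand from the rotatability rule and the
    heavy-atom graph, and are re-verified against the brute-force paths
    in the test suite.
    """

    name: str
    smiles: str
    n_bits: int
    group_order: int
    note: str = ""


def molecule_fixtures() -> dict[str, MoleculeFixture]:
    return {
        f.name: f
        for f in (
            MoleculeFixture(
                name="benzene",
                smiles="c1ccccc1",
                n_bits=0,
                group_order=1,
                note="all bonds are ring bonds: no torsion bits, nTABS = 1",
            ),
            MoleculeFixture(
                name="n-butane",
                smiles="CCCC",
                n_bits=1,
                group_order=1,
                note="only the central C-C bond has a heavy neighbor on "
                "both sides; the end-to-end flip fixes that single bit",
            ),
            MoleculeFixture(
                name="ethyl benzoate",
                smiles="CCOC(=O)c1ccccc1",
                n_bits=3,
                group_order=1,
                note="drug-like asymmetric molecule: the phenyl flip is a "
                "non-trivial atom automorphism projecting to the identity "
                "bit permutation",
            ),
            MoleculeFixture(
                name="1,2-diphenylethane",
                smiles="c1ccccc1CCc1ccccc1",
                n_bits=3,
                group_order=2,
                note="the end-to-end flip exchanges the two phenyl-CH2 "
                "bits and fixes the central bit",
            ),
        )
    }


def synthetic_ensemble(
    system: TabsSystem,
    n_conformers: int,
    seed: int | np.random.Generator = 0,
    same_loc: float = 0.95,
    diff_loc: float = 0.60,
    scale: float = 0.05,
) -> tuple[dict[str, str], list[PairScore]]:
    """Label-level conformer ensemble with a controllable score structure.

    Samples ``n_conformers`` rawTABS uniformly from S, canonicalizes
    them to TABS labels, and draws a similarity score for every
    unordered pair: Normal(*same_loc*, *scale*) for equal-TABS pairs,
    Normal(*diff_loc*, *scale*) for unequal ones, clipped to [0, 1].
    ``scale=0`` gives perfectly separated score distributions; growing
    *scale* (or shrinking the gap) makes the two classes overlap.

    Returns (labels by conformer id, pair-score table) — exactly the
    inputs of the categorization framework.
    """
    if n_conformers < 2:
        raise ValueError("need at least 2 conformers to form a pair")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    labels = {
        f"c{k}": str(canonical_tabs(random_rawtabs(system, rng), system.group))
        for k in range(n_conformers)
    }
    pairs = []
    for i, j in combinations(sorted(labels), 2):
        loc = same_loc if labels[i] == labels[j] else diff_loc
        value = loc if scale == 0 else float(rng.normal(loc, scale))
        pairs.append(PairScore(i, j, float(np.clip(value, 0.0, 1.0))))
    return labels, pairs
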