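"""Fixpoint counting, Burnside orbit counting, and the group machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tabscount.bitstrings import (
    RawTABS,
    TabsSystem,
    apply_permutation,
    cardinality,
    enumerate_rawtabs,
)
from tabscount.burnside import (
    BitPermutation,
    GroupClosureError,
    MultiplicityMismatchError,
    SymmetryGroup,
    fixpoint_count,
    ntabs_burnside,
    ntabs_naive,
    stabilizer,
)
from tabscount.fixtures import SystemSpec, random_system


def brute_force_fixpoints(g, multiplicities):
    """Independent oracle: count strings with g*s == s by enumeration."""
    system = TabsSystem(multiplicities=multiplicities)
    return sum(1 for s in enumerate_rawtabs(system) if apply_permutation(s, g) == s)


class TestBitPermutation:
    def test_from_cycles_and_call(self):
        g = BitPermutation.from_cycles(4, (1, 2, 3))
        assert [g(i) for i in (1, 2, 3, 4)] == [2, 3, 1, 4]
        assert g.cycles() == [(0, 1, 2), (3,)]

    def test_compose_and_inverse(self):
        g = BitPermutation.from_cycles(3, (1, 2, 3))
        assert g.compose(g.inverse()).is_identity
        assert g.compose(g).compose(g).is_identity

    def test_rejects_non_bijection(self):
        with pytest.raises(ValueError):
            BitPermutation((0, 0, 1))


class TestSymmetryGroup:
    def test_closure_from_generator(self):
        g = SymmetryGroup.from_generators([BitPermutation.from_cycles(3, (1, 2, 3))])
        assert g.order == 3

    def test_full_symmetric_group(self):
        gens = [
            BitPermutation.from_cycles(3, (1, 2)),
            BitPermutation.from_cycles(3, (1, 2, 3)),
        ]
        assert SymmetryGroup.from_generators(gens).order == 6

    def test_non_closed_set_rejected(self):
        # {I, (123)} misses (132): not closed under composition
        with pytest.raises(GroupClosureError):
            SymmetryGroup(
                [BitPermutation.identity(3), BitPermutation.from_cycles(3, (1, 2, 3))]
            )

    def test_missing_identity_rejected(self):
        with pytest.raises(GroupClosureError):
            SymmetryGroup([BitPermutation.from_cycles(2, (1, 2))])

    def test_closure_cap(self):
        gens = [
            BitPermutation.from_cycles(8, (1, 2)),
            BitPermutation.from_cycles(8, tuple(range(1, 9))),
        ]
        with pytest.raises(GroupClosureError, match="cap"):
            SymmetryGroup.from_generators(gens, max_order=100)


class TestFixpointCount:
    def test_identity_counts_everything(self):
        assert fixpoint_count(BitPermutation.identity(2), (3, 3)) == 9

    @pytest.mark.parametrize(
        "cycles, mults",
        [
            ([(1, 2)], (3, 3)),
            ([(1, 2, 3)], (2, 2, 2, 5)),
            ([(1, 3), (2, 4)], (2, 3, 2, 3)),
        ],
    )
    def test_matches_brute_force(self, cycles, mults):
        g = BitPermutation.from_cycles(len(mults), *cycles)
        assert fixpoint_count(g, mults) == brute_force_fixpoints(g, mults)

    def test_cycle_product_rule(self):
        # one 3-cycle over multiplicity 2 plus a fixed multiplicity-5 bit
        g = BitPermutation.from_cycles(4, (1, 2, 3))
        assert fixpoint_count(g, (2, 2, 2, 5)) == 10

    def test_mixed_multiplicity_cycle_is_an_error(self):
        g = BitPermutation.from_cycles(2, (1, 2))
        with pytest.raises(MultiplicityMismatchError):
            fixpoint_count(g, (2, 3))


class TestNtabs:
    def test_trivial_group_gives_cardinality(self, fig2):
        trivial = TabsSystem(multiplicities=(3, 3))
        assert ntabs_burnside(trivial) == cardinality(trivial) == 9

    def test_fig2_swap_group(self, fig2):
        assert ntabs_burnside(fig2) == 6
        assert ntabs_naive(fig2) == 6

    def test_empty_system(self):
        assert ntabs_burnside(TabsSystem(multiplicities=())) == 1

    def test_multisets_under_full_symmetric_group(self):
        gens = [
            BitPermutation.from_cycles(3, (1, 2)),
            BitPermutation.from_cycles(3, (1, 2, 3)),
        ]
        system = TabsSystem(
            multiplicities=(2, 2, 2), group=SymmetryGroup.from_generators(gens)
        )
        # orbits = multisets of size 3 over 2 values
        assert ntabs_burnside(system) == ntabs_naive(system) == 4


class TestStabilizer:
    def test_constant_string_full_group(self, fig2):
        assert len(stabilizer(RawTABS((2, 2)), fig2.group)) == 2

    def test_asymmetric_string_trivial_stabilizer(self, fig2):
        stab = stabilizer(RawTABS((1, 2)), fig2.group)
        assert len(stab) == 1 and next(iter(stab)).is_identity

    def test_trivial_group(self):
        group = SymmetryGroup.trivial(3)
        assert len(stabilizer(RawTABS((1, 2, 3)), group)) == 1


SEEDS = st.integers(min_value=0, max_value=2**31 - 1)


@given(seed=SEEDS)
def test_oracle_equivalence_random_systems(seed):
    """Burnside count equals brute-force enumerate-and-deduplicate."""
    rng = np.random.default_rng(seed)
    n_gens = int(rng.integers(0, 4))
    system = random_system(SystemSpec(n_generators=n_gens), rng)
    assert ntabs_burnside(system) == ntabs_naive(system, cap=10**5)


@given(seed=SEEDS)
def test_burnside_sum_divisible_and_bounded(seed):
    rng = np.random.default_rng(seed)
    system = random_system(SystemSpec(n_generators=3), rng)
    total = sum(fixpoint_count(g, system.multiplicities) for g in system.group)
    assert total % system.group.order == 0
    n = ntabs_burnside(system)
    m = cardinality(system)
    assert m / system.group.order <= n <= m


def test_corrupted_group_detected_by_exact_division():
    """A non-closed element multiset makes the Burnside division inexact."""

    class FakeGroup:
        # claims order 5 but only contributes fixpoint sum 9 + 3 = 12,
        # which 5 does not divide — the self-check must fire
        def __iter__(self):
            return iter(
                [
                    BitPermutation.identity(2),
                    BitPermutation.from_cycles(2, (1, 2)),
                ]
            )

        order = 5
        degree = 2

    class FakeSystem:
        multiplicities = (3, 3)
        group = FakeGroup()

    with pytest.raises(GroupClosureError, match="not divisible"):
        ntabs_burnside(FakeSystem())


def test_astronomical_system_is_cheap():
    """A system far beyond enumeration reach still counts exactly."""
    n = 40
    mults = (4,) * n
    rotate = BitPermutation.from_cycles(n, tuple(range(1, n + 1)))
    system = TabsSystem(
        multiplicities=mults, group=SymmetryGroup.from_generators([rotate])
    )
    result = ntabs_burnside(system)
    # necklace count: (1/n) sum_{d|n} phi(n/d) 4^d
    from math import gcd

    expected = sum(4 ** gcd(k, n) for k in range(n)) // n
    assert result == expected
    assert result > 10**22
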