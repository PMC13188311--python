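"""Torsion perception, pattern matching, and angular binning."""

import numpy as np
import pytest
import yaml
from rdkit import Chem

from tabscount.torsionlib import (
    LibraryError,
    NoMatchError,
    TorsionPattern,
    assign_bin,
    assign_patterns,
    default_library,
    find_rotatable_torsions,
    load_library,
    match_pattern,
    mol_from_smiles,
    read_molecules,
)

GENERIC = TorsionPattern(
    pattern_id="generic",
    smarts="[!#1:1]~[*:2]-!@[*:3]~[!#1:4]",
    boundaries=(-120.0, 0.0, 120.0),
    priority=99,
)


@pytest.mark.parametrize(
    "smiles, expected_bits",
    [
        ("CC", 0),  # ethane: no heavy neighbor beyond the bond
        ("CCCC", 1),  # n-butane: only the central bond qualifies
        ("c1ccccc1", 0),  # benzene: ring bonds only
        ("C/C=C/C", 0),  # 2-butene: double bond is not rotatable
        ("CCOC(=O)c1ccccc1", 3),  # ethyl benzoate
        ("c1ccccc1CCc1ccccc1", 3),  # 1,2-diphenylethane
    ],
)
def test_rotatable_torsion_counts(smiles, expected_bits):
    bits = find_rotatable_torsions(mol_from_smiles(smiles))
    assert len(bits) == expected_bits
    assert [b.bit_index for b in bits] == list(range(len(bits)))


def test_quadruple_atoms_are_bonded_chain():
    mol = mol_from_smiles("CCOC(=O)c1ccccc1")
    for bit in find_rotatable_torsions(mol):
        a, b, c, d = bit.quadruple
        assert len({a, b, c, d}) == 4
        assert {b, c} == set(bit.bond)
        assert mol.GetBondBetweenAtoms(a, b) is not None
        assert mol.GetBondBetweenAtoms(c, d) is not None


class TestMatchPattern:
    def test_butane_central_bond_is_sp3_sp3(self):
        [bit] = find_rotatable_torsions(mol_from_smiles("CCCC"))
        pattern = match_pattern(bit, default_library())
        assert pattern.pattern_id == "sp3_sp3"
        assert pattern.multiplicity == 3

    def test_biphenyl_bond_beats_generic(self):
        [bit] = find_rotatable_torsions(mol_from_smiles("c1ccccc1-c1ccccc1"))
        pattern = match_pattern(bit, default_library())
        assert pattern.pattern_id == "aromatic_aromatic"
        assert pattern.multiplicity == 4

    def test_amide_bond(self):
        mol = mol_from_smiles("CC(=O)NC")
        bits = find_rotatable_torsions(mol)
        matched = {match_pattern(b, default_library()).pattern_id for b in bits}
        assert "amide" in matched

    def test_catch_all_only_library(self):
        [bit] = find_rotatable_torsions(mol_from_smiles("CCCC"))
        assert match_pattern(bit, [GENERIC]).pattern_id == "generic"

    def test_no_match_without_catch_all(self):
        aromatic_only = [p for p in default_library() if p.pattern_id == "aromatic_aromatic"]
        [bit] = find_rotatable_torsions(mol_from_smiles("CCCC"))
        with pytest.raises(NoMatchError):
            match_pattern(bit, aromatic_only)

    def test_assign_patterns_fills_multiplicities(self):
        bits = assign_patterns(
            find_rotatable_torsions(mol_from_smiles("CCOC(=O)c1ccccc1")),
            default_library(),
        )
        assert all(b.multiplicity and b.pattern_id for b in bits)


class TestAssignBin:
    three_bin = GENERIC  # boundaries -120, 0, 120

    def test_wrap_bin_contains_180(self):
        assert assign_bin(180.0, self.three_bin) == 1
        assert assign_bin(-120.0, self.three_bin) == 1  # upper edge of wrap

    def test_interior_bins(self):
        assert assign_bin(60.0, self.three_bin) == 3  # (0, 120]
        assert assign_bin(0.0, self.three_bin) == 2  # upper edge of (-120, 0]
        assert assign_bin(-60.0, self.three_bin) == 2

    def test_one_bin_pattern_is_constant(self):
        whole = TorsionPattern("whole", "[!#1:1]~[*:2]-!@[*:3]~[!#1:4]", (180.0,), 0)
        for angle in (-179.9, -1.0, 0.0, 90.0, 180.0):
            assert assign_bin(angle, whole) == 1

    @pytest.mark.parametrize("bad", [-180.0, -200.0, 181.0, 360.0])
    def test_unnormalized_angle_rejected(self, bad):
        with pytest.raises(ValueError, match="normalized"):
            assign_bin(bad, self.three_bin)


class TestLibrary:
    def test_shipped_patterns_cover_the_circle(self):
        for pattern in default_library():
            assert pytest.approx(sum(pattern.bin_arcs())) == 360.0
            assert pattern.multiplicity == len(pattern.boundaries)

    def test_assign_bin_surjective_for_every_pattern(self):
        grid = np.linspace(-179.9, 180.0, 720)
        for pattern in default_library():
            hit = {assign_bin(float(a), pattern) for a in grid}
            assert hit == set(range(1, pattern.multiplicity + 1))

    def test_catch_all_is_last(self):
        library = default_library()
        assert library[-1].pattern_id == "generic"

    def test_user_library_round_trip(self, tmp_path):
        path = tmp_path / "lib.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "patterns": [
                        {
                            "id": "generic",
                            "smarts": "[!#1:1]~[*:2]-!@[*:3]~[!#1:4]",
                            "boundaries": [-120.0, 0.0, 120.0],
                        }
                    ]
                }
            )
        )
        [pattern] = load_library(path)
        assert pattern.multiplicity == 3

    @pytest.mark.parametrize(
        "boundaries", [[], [0.0, 0.0], [120.0, -120.0], [-190.0, 0.0]]
    )
    def test_invalid_boundaries_rejected(self, boundaries):
        with pytest.raises(LibraryError):
            TorsionPattern("bad", "[!#1:1]~[*:2]-!@[*:3]~[!#1:4]", tuple(boundaries), 0)

    def test_smarts_must_map_four_atoms(self):
        with pytest.raises(LibraryError, match="map"):
            TorsionPattern("bad", "[*:1][*:2]", (-90.0, 90.0), 0)


def test_layout_invariant_under_atom_relabeling():
    """Renumbering atoms must not change the bit layout (up to symmetry)."""
    mol = mol_from_smiles("CCOC(=O)c1ccccc1")
    order = list(range(mol.GetNumAtoms()))[::-1]
    renumbered = Chem.RenumberAtoms(mol, order)
    bits_a = assign_patterns(find_rotatable_torsions(mol), default_library())
    bits_b = assign_patterns(find_rotatable_torsions(renumbered), default_library())
    # old index o sits at new position order.index(o)
    to_new = {o: order.index(o) for o in range(mol.GetNumAtoms())}
    mapped = sorted(
        tuple(sorted((to_new[b.bond[0]], to_new[b.bond[1]]))) for b in bits_a
    )
    assert mapped == sorted(b.bond for b in bits_b)
    assert [b.pattern_id for b in bits_a] == [b.pattern_id for b in bits_b]


def test_read_molecules_smiles_and_sdf(tmp_path):
    smi = tmp_path / "mols.smi"
    smi.write_text("CCCC butane\nc1ccccc1 benzene\n")
    mols = read_molecules(smi)
    assert [name for name, _ in mols] == ["butane", "benzene"]
    assert mols[0][1].GetNumAtoms() == 4

    sdf = tmp_path / "mols.sdf"
    writer = Chem.SDWriter(str(sdf))
    mol = Chem.AddHs(mol_from_smiles("CCCC"))
    Chem.AllChem.EmbedMolecule(mol, randomSeed=11)
    mol.SetProp("_Name", "butane3d")
    writer.write(mol)
    writer.close()
    [(name, loaded)] = read_molecules(sdf)
    assert name == "butane3d"
    assert loaded.GetNumConformers() == 1
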