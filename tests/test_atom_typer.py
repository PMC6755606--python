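"""Atom typer: perception, family classifiers, code assembly, holograms."""

import pytest
from rdkit import Chem

import jplogp as jp
from jplogp.atom_typer import decode

from conftest import typed


def atom_of(smiles: str, symbol: str, index: int = 0) -> tuple[Chem.Atom, Chem.Mol]:
    mol = jp.perceive(smiles)
    hits = [a for a in mol.GetAtoms() if a.GetSymbol() == symbol]
    return hits[index], mol


# --------------------------------------------------------------------------
# perception
# --------------------------------------------------------------------------

class TestPerceive:
    def test_benzene_atoms_and_aromaticity(self):
        mol = jp.perceive("c1ccccc1")
        carbons = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
        hydrogens = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 1]
        assert len(carbons) == 6 and len(hydrogens) == 6
        assert all(a.GetIsAromatic() for a in carbons)
        assert all(a.GetFormalCharge() == 0 for a in mol.GetAtoms())

    def test_formal_charge_preserved_and_encoded(self):
        h = typed("[O-]C(=O)C")
        charged = [code for code in h if decode(code)[0] == -1]
        assert len(charged) == 1
        _, z, _, _ = decode(charged[0])
        assert z == 8
        assert charged[0] < 100_000  # A digit is 0 for a -1 charge

    def test_transition_metal_accepted_z_boundary_rejected(self):
        ferroceneish = jp.perceive("[Fe]")  # Z=26 fits the two-digit field
        assert ferroceneish.GetNumAtoms() == 1
        with pytest.raises(jp.UnsupportedElementError):
            jp.perceive("[Rf]")  # Z=104

    def test_parse_failure_raises_input_error(self):
        with pytest.raises(jp.ParseError):
            jp.perceive("not-a-smiles((((")

    def test_salt_stripped_to_largest_fragment(self):
        mol = jp.perceive("CC(=O)[O-].[Na+]")
        symbols = sorted(a.GetSymbol() for a in mol.GetAtoms() if a.GetAtomicNum() > 1)
        assert "Na" not in symbols
        assert symbols.count("C") == 2


# --------------------------------------------------------------------------
# polar neighbours
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "smiles, symbol, index, expected",
    [
        ("CC(C)=O", "C", 1, 1),          # acetone central carbon: one O
        ("FC(F)(F)F", "C", 0, 0),        # fluorine is not polar here
        ("O=P(O)(O)O", "P", 0, 4),       # phosphate: four oxygens
        ("CCN(CC)CC", "N", 0, 0),        # amine N has only carbon neighbours
        ("NN", "N", 0, 1),               # hydrazine: N neighbour is polar
    ],
)
def test_polar_neighbor_count(smiles, symbol, index, expected):
    atom, mol = atom_of(smiles, symbol, index)
    assert jp.polar_neighbor_count(atom, mol) == expected


# --------------------------------------------------------------------------
# carbon classifier
# --------------------------------------------------------------------------

class TestCarbon:
    def test_methane_is_sp3_no_polar(self):
        atom, mol = atom_of("C", "C")
        env = jp.classify_carbon(atom, mol)
        assert env.family == "carbon" and env.dd == 2

    def test_sp3_polar_split(self):
        polar, mol = atom_of("CO", "C")
        assert jp.classify_carbon(polar, mol).dd == 3

    def test_pyridine_alpha_differs_from_aniline_ipso(self):
        # polar pulled through the aromatic system vs hung off a single bond
        mol_py = jp.perceive("c1ccncc1")
        alpha = next(
            a for a in mol_py.GetAtoms()
            if a.GetAtomicNum() == 6
            and any(n.GetAtomicNum() == 7 for n in a.GetNeighbors())
        )
        mol_an = jp.perceive("Nc1ccccc1")
        ipso = next(
            a for a in mol_an.GetAtoms()
            if a.GetAtomicNum() == 6
            and any(n.GetAtomicNum() == 7 for n in a.GetNeighbors())
        )
        assert jp.classify_carbon(alpha, mol_py).dd != jp.classify_carbon(ipso, mol_an).dd

    def test_carbonyl_carbon_in_double_bond_group_with_multiply_bound_polar(self):
        atom, mol = atom_of("CC(C)=O", "C", 1)
        env = jp.classify_carbon(atom, mol)
        assert "double" in env.label
        assert env.dd == 34  # double-bond base + one multiply-bound polar

    def test_nitrile_carbon_triple_group(self):
        atom, mol = atom_of("CC#N", "C", 1)
        env = jp.classify_carbon(atom, mol)
        assert "triple" in env.label

    def test_rejects_non_carbon(self):
        atom, mol = atom_of("O", "O")
        with pytest.raises(jp.TyperError):
            jp.classify_carbon(atom, mol)


# --------------------------------------------------------------------------
# nitrogen classifier
# --------------------------------------------------------------------------

class TestNitrogen:
    def test_aniline_and_amide_share_delocalized_family(self):
        aniline_n, m1 = atom_of("Nc1ccccc1", "N")
        amide_n, m2 = atom_of("CC(N)=O", "N")
        e1, e2 = jp.classify_nitrogen(aniline_n, m1), jp.classify_nitrogen(amide_n, m2)
        assert e1.dd == e2.dd == 1

    def test_thioamide_nitrogen_is_delocalized(self):
        atom, mol = atom_of("CC(N)=S", "N")
        assert jp.classify_nitrogen(atom, mol).dd == 1

    def test_triethylamine_plain_sp3(self):
        atom, mol = atom_of("CCN(CC)CC", "N")
        env = jp.classify_nitrogen(atom, mol)
        assert env.dd == 3 and "single" in env.label

    def test_hydrazine_polar_bound(self):
        atom, mol = atom_of("NN", "N")
        assert jp.classify_nitrogen(atom, mol).dd == 2

    def test_pyridine_nitrogen_not_aniline_like(self):
        atom, mol = atom_of("c1ccncc1", "N")
        env = jp.classify_nitrogen(atom, mol)
        assert env.dd not in (1, 2)


# --------------------------------------------------------------------------
# oxygen classifier
# --------------------------------------------------------------------------

class TestOxygen:
    def test_nitro_oxygen_bound_to_nitrogen(self):
        atom, mol = atom_of("C[N+](=O)[O-]", "O", 0)
        assert jp.classify_oxygen(atom, mol).dd == 1

    def test_sulfoxide_oxygen_bound_to_sulfur(self):
        atom, mol = atom_of("CS(C)=O", "O")
        assert jp.classify_oxygen(atom, mol).dd == 2

    def test_ester_vs_amide_carbonyl_oxygens_differ(self):
        ester_h = typed("COC(C)=O")
        amide_h = typed("CNC(C)=O")
        ester_sp2 = {c for c in ester_h if decode(c)[1] == 8 and decode(c)[3] == 5}
        amide_sp2 = {c for c in amide_h if decode(c)[1] == 8 and decode(c)[3] == 3}
        assert ester_sp2 and amide_sp2

    def test_acid_vs_ester_carbonyl_differ(self):
        def sp2_dd(smiles):
            mol = jp.perceive(smiles)
            for a in mol.GetAtoms():
                if a.GetAtomicNum() == 8 and any(
                    b.GetBondType() == Chem.BondType.DOUBLE for b in a.GetBonds()
                ):
                    return jp.classify_oxygen(a, mol).dd
        assert sp2_dd("CC(=O)O") == 4
        assert sp2_dd("COC(C)=O") == 5

    def test_thioester_carbonyl_oxygen_separated(self):
        atom, mol = atom_of("CSC(C)=O", "O")
        assert jp.classify_oxygen(atom, mol).dd == 7

    def test_phenol_hydroxyl_and_anisole_ether(self):
        phenol_o, m1 = atom_of("Oc1ccccc1", "O")
        anisole_o, m2 = atom_of("COc1ccccc1", "O")
        assert jp.classify_oxygen(phenol_o, m1).dd == 8
        assert jp.classify_oxygen(anisole_o, m2).dd == 9


# --------------------------------------------------------------------------
# fluorine classifier
# --------------------------------------------------------------------------

class TestFluorine:
    def test_aromatic_vs_sp3_carrier(self):
        f_ar, m1 = atom_of("Fc1ccccc1", "F")
        f_sp3, m2 = atom_of("CCF", "F")
        assert jp.classify_fluorine(f_ar, m1).dd != jp.classify_fluorine(f_sp3, m2).dd

    def test_cf3_fluorines_identical_count_three(self):
        h = typed("FC(F)(F)c1ccccc1")
        f_codes = {c: n for c, n in h.items() if decode(c)[1] == 9}
        assert len(f_codes) == 1
        assert next(iter(f_codes.values())) == 3

    def test_withdrawing_count_distinguishes_cf4_from_ch3f(self):
        f4, m1 = atom_of("FC(F)(F)F", "F")
        f1, m2 = atom_of("CF", "F")
        e4, e1 = jp.classify_fluorine(f4, m1), jp.classify_fluorine(f1, m2)
        assert e4.dd != e1.dd
        assert e4.dd - e1.dd == 3  # three extra withdrawing substituents

    def test_non_carbon_carrier_residual_class(self):
        atom, mol = atom_of("FS(F)(F)(F)(F)F", "F")
        assert jp.classify_fluorine(atom, mol).dd == 0


# --------------------------------------------------------------------------
# hydrogen classifier
# --------------------------------------------------------------------------

class TestHydrogen:
    def test_aromatic_vs_sp3_carrier(self):
        h_benzene = typed("c1ccccc1")
        h_methane = typed("C")
        benzene_h = {c for c in h_benzene if decode(c)[1] == 1}
        methane_h = {c for c in h_methane if decode(c)[1] == 1}
        assert benzene_h.isdisjoint(methane_h)

    def test_hydroxyl_vs_carbon_hydrogen(self):
        h = typed("CO")  # methanol
        h_codes = {c: n for c, n in h.items() if decode(c)[1] == 1}
        assert len(h_codes) == 2  # C-H class and O-H class
        assert sorted(h_codes.values()) == [1, 3]

    def test_benzene_hydrogens_one_class_count_six(self):
        h = typed("c1ccccc1")
        h_codes = {c: n for c, n in h.items() if decode(c)[1] == 1}
        assert list(h_codes.values()) == [6]


# --------------------------------------------------------------------------
# default classifier
# --------------------------------------------------------------------------

class TestDefault:
    def test_chlorophenol_chlorine(self):
        atom, mol = atom_of("Oc1ccc(Cl)cc1", "Cl")
        env = jp.classify_default(atom, mol)
        assert env.family == "default" and env.dd == 0

    def test_thiophene_sulfur_aromatic(self):
        atom, mol = atom_of("c1ccsc1", "S")
        assert jp.classify_default(atom, mol).dd == 50

    def test_sulfonamide_sulfur_polar_count(self):
        atom, mol = atom_of("NS(=O)(=O)c1ccc(N)cc1", "S")
        assert jp.classify_default(atom, mol).dd == 3  # two O plus one N


# --------------------------------------------------------------------------
# code assembly + molecule holograms
# --------------------------------------------------------------------------

class TestTypeAtomAndMolecule:
    def test_methane_carbon_code_fields(self):
        atom, mol = atom_of("C", "C")
        code = jp.type_atom(atom, mol)
        charge, z, heavy, dd = decode(code)
        assert (charge, z, heavy, dd) == (0, 6, 0, 2)

    def test_phenolate_negative_charge_leading_digit(self):
        h = typed("[O-]c1ccccc1")
        anion = [c for c in h if decode(c)[1] == 8]
        assert len(anion) == 1 and anion[0] < 100_000

    def test_charge_below_minus_one_rejected(self):
        mol = Chem.MolFromSmiles("[O-2]", sanitize=False)
        atom = mol.GetAtomWithIdx(0)
        with pytest.raises(jp.ChargeRangeError):
            jp.type_atom(atom, mol)

    def test_benzene_hologram_two_codes(self):
        h = typed("c1ccccc1")
        assert sorted(h.values()) == [6, 6] and len(h) == 2

    def test_methane_hologram(self):
        h = typed("C")
        assert sorted(h.values()) == [1, 4]

    def test_count_conservation_includes_hydrogens(self):
        for smiles in ["CCO", "c1ccncc1", "CC(N)=O", "FC(F)(F)c1ccccc1"]:
            mol = jp.perceive(smiles)
            assert sum(typed(smiles).values()) == mol.GetNumAtoms()

    def test_halogen_swap_changes_exactly_one_heavy_code(self):
        h_cl = typed("Oc1ccc(Cl)cc1")
        h_br = typed("Oc1ccc(Br)cc1")
        delta = jp.difference(h_br, h_cl)
        assert len(delta) == 2
        assert sorted(delta.values()) == [-1, 1]
        touched = {decode(c)[1] for c in delta}
        assert touched == {17, 35}  # only the halogen identity differs

    def test_typing_invariant_under_atom_renumbering(self):
        base = Chem.MolFromSmiles("CC(=O)Nc1ccc(O)cc1")  # paracetamol
        reference = jp.type_molecule(jp.perceive(base))
        n = base.GetNumAtoms()
        import random

        rng = random.Random(42)
        for _ in range(5):
            order = list(range(n))
            rng.shuffle(order)
            shuffled = Chem.RenumberAtoms(base, order)
            smiles = Chem.MolToSmiles(shuffled, canonical=False)
            assert jp.type_structure(smiles) == reference
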