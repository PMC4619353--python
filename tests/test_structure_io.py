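"""Reading, cleaning, charging, locus identification and in-silico mutation."""

import numpy as np
import pytest

from gagsite import (
    ChargedStructure,
    assign_charges,
    clean_structure,
    identify_loci,
    load_charge_model,
    mutate_residue,
    read_structure,
    write_pdb,
)
from gagsite.structures import (
    EmptySelectionError,
    ResidueNotFoundError,
    StructureError,
    FORMAL_CHARGES,
    NEUTRAL_DONOR_CATALOG_STRICT,
)

from conftest import make_atom


class TestReadStructure:
    def test_identity_read(self, two_model_pdb):
        s = read_structure(two_model_pdb)
        assert len(s) == 2
        assert s.atoms[0].coords == (0.0, 0.0, 0.0)
        assert s.atoms[1].coords == (3.8, 0.0, 0.0)
        assert all(a.partial_charge == 0.0 for a in s.atoms)

    def test_model_selection(self, two_model_pdb):
        s = read_structure(two_model_pdb, model_index=2)
        assert len(s) == 2
        assert all(a.coords[2] == 9.0 for a in s.atoms)

    def test_chain_filter(self, messy_pdb):
        s = read_structure(messy_pdb, chains={"B"})
        assert {a.chain_id for a in s.atoms} == {"B"}

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureError):
            read_structure(tmp_path / "nope.pdb")

    def test_empty_selection(self, messy_pdb):
        with pytest.raises(EmptySelectionError):
            read_structure(messy_pdb, chains={"Z"})


class TestCleanStructure:
    def test_waters_het_hydrogens_altlocs(self, messy_pdb):
        s = clean_structure(read_structure(messy_pdb))
        names = [(a.residue_name, a.name) for a in s.atoms]
        # waters gone, ligand gone, hydrogen gone, one ND2 conformer kept
        assert ("HOH", "O") not in names
        assert ("LIG", "C1") not in names
        assert ("ASN", "H") not in names
        assert names.count(("ASN", "ND2")) == 1
        kept_nd2 = [a for a in s.atoms if a.name == "ND2"][0]
        assert kept_nd2.alt_loc == "A"  # first-listed conformer wins

    def test_keep_het_flag(self, messy_pdb):
        s = clean_structure(read_structure(messy_pdb), keep_het=True)
        assert any(a.residue_name == "LIG" for a in s.atoms)
        assert not any(a.is_water for a in s.atoms)  # waters always removed

    def test_identity_when_nothing_removable(self):
        s = ChargedStructure([make_atom(1, "CA", "GLY"), make_atom(2, "CA", "GLY", resnum=2)])
        out = clean_structure(s)
        assert [(a.name, a.coords) for a in out.atoms] == [
            (a.name, a.coords) for a in s.atoms
        ]


class TestAssignCharges:
    def test_formal_model_examples(self):
        gly = ChargedStructure(
            [make_atom(i, "CA", "GLY", resnum=i) for i in range(1, 4)]
        )
        charged = assign_charges(gly, load_charge_model("formal"))
        assert charged.net_charge == 0.0

        lys = ChargedStructure(
            [
                make_atom(1, "CA", "LYS"),
                make_atom(2, "CE", "LYS"),
                make_atom(3, "NZ", "LYS", coords=(1, 0, 0), element="N"),
            ]
        )
        charged = assign_charges(lys, load_charge_model("formal"))
        by_name = {a.name: a.partial_charge for a in charged.atoms}
        assert by_name == {"CA": 0.0, "CE": 0.0, "NZ": 1.0}

    def test_idempotent(self, messy_pdb):
        s = clean_structure(read_structure(messy_pdb))
        model = load_charge_model("charmm-like")
        once = assign_charges(s, model)
        twice = assign_charges(once, model)
        assert [a.partial_charge for a in once.atoms] == [
            a.partial_charge for a in twice.atoms
        ]

    @pytest.mark.parametrize("name", ["formal", "mmff94-like", "charmm-like"])
    def test_template_sums_match_formal_charges(self, name):
        model = load_charge_model(name)
        model.validate()  # raises if any residue is off by > 0.01 e
        for res, tmpl in model.residue_templates.items():
            assert abs(sum(tmpl.values()) - FORMAL_CHARGES.get(res, 0)) <= 0.01

    def test_arg_sidechain_sums_to_plus_one(self):
        model = load_charge_model("charmm-like")
        tmpl = model.residue_templates["ARG"]
        sidechain = sum(q for a, q in tmpl.items() if a not in ("N", "CA", "C", "O"))
        assert sidechain == pytest.approx(1.0, abs=0.01)

    def test_formal_net_charge_counts_residues(self):
        atoms = [
            make_atom(1, "NZ", "LYS", resnum=1, element="N"),
            make_atom(2, "NH1", "ARG", resnum=2, coords=(5, 0, 0), element="N"),
            make_atom(3, "NH2", "ARG", resnum=2, coords=(6, 0, 0), element="N"),
            make_atom(4, "OD1", "ASP", resnum=3, coords=(9, 0, 0), element="O"),
            make_atom(5, "OD2", "ASP", resnum=3, coords=(10, 0, 0), element="O"),
            make_atom(6, "CA", "GLY", resnum=4, coords=(13, 0, 0)),
        ]
        s = assign_charges(ChargedStructure(atoms), load_charge_model("formal"))
        # (#Arg + #Lys) - (#Asp + #Glu) = (1 + 1) - (1 + 0) = 1
        assert s.net_charge == pytest.approx(1.0, abs=1e-12)


class TestIdentifyLoci:
    def _asn(self):
        return ChargedStructure(
            [
                make_atom(1, "CA", "ASN"),
                make_atom(2, "ND2", "ASN", coords=(1.4, 0, 0), element="N"),
            ]
        )

    def test_single_asn_gives_nd2(self):
        loci = identify_loci(self._asn(), "neutral_donor")
        assert [l.atom_ref[3] for l in loci] == ["ND2"]
        assert loci[0].label == "A:ASN 1:ND2"

    def test_poly_gly_empty(self):
        s = ChargedStructure([make_atom(i, "CA", "GLY", resnum=i) for i in range(1, 5)])
        assert identify_loci(s, "neutral_donor") == []

    def test_arg_lys_basic_catalog(self):
        atoms = [
            make_atom(1, "NE", "ARG", resnum=1, element="N"),
            make_atom(2, "NH1", "ARG", resnum=1, coords=(1, 0, 0), element="N"),
            make_atom(3, "NH2", "ARG", resnum=1, coords=(2, 0, 0), element="N"),
            make_atom(4, "NZ", "LYS", resnum=2, coords=(5, 0, 0), element="N"),
        ]
        loci = identify_loci(ChargedStructure(atoms), "basic_donor")
        assert [l.atom_ref[3] for l in loci] == ["NE", "NH1", "NH2", "NZ"]

    def test_atom_order_invariance(self, specific_structure):
        shuffled = ChargedStructure(
            list(reversed([a for a in specific_structure.copy().atoms])),
            charge_model=specific_structure.charge_model,
        )
        a = identify_loci(specific_structure, "neutral_donor")
        b = identify_loci(shuffled, "neutral_donor")
        assert [l.label for l in a] == [l.label for l in b]

    def test_his_excluded_when_charged(self):
        his = [
            make_atom(1, "ND1", "HIS", element="N"),
            make_atom(2, "NE2", "HIS", coords=(2, 0, 0), element="N"),
        ]
        neutral = ChargedStructure(his)
        assert len(identify_loci(neutral, "neutral_donor")) == 2
        charged = assign_charges(neutral, load_charge_model("formal", his_charged=True))
        assert identify_loci(charged, "neutral_donor") == []

    def test_strict_catalog_excludes_ser(self):
        s = ChargedStructure([make_atom(1, "OG", "SER", element="O")])
        assert len(identify_loci(s, "neutral_donor")) == 1
        assert (
            identify_loci(s, "neutral_donor", catalog=NEUTRAL_DONOR_CATALOG_STRICT) == []
        )


class TestMutateResidue:
    def _asn_structure(self):
        return assign_charges(
            ChargedStructure(
                [
                    make_atom(1, "CA", "ASN"),
                    make_atom(2, "CB", "ASN", coords=(1.5, 0, 0)),
                    make_atom(3, "ND2", "ASN", coords=(2.5, 1, 0), element="N"),
                ]
            ),
            load_charge_model("formal"),
        )

    def test_to_ala_removes_donor_locus(self):
        mutated = mutate_residue(self._asn_structure(), "A", 1, "to_ala")
        assert identify_loci(mutated, "neutral_donor") == []
        assert all(a.residue_name == "ALA" for a in mutated.atoms)
        assert {a.name for a in mutated.atoms} == {"CA", "CB"}

    def test_to_ala_on_ala_is_identity(self):
        ala = ChargedStructure(
            [make_atom(1, "CA", "ALA"), make_atom(2, "CB", "ALA", coords=(1.5, 0, 0))]
        )
        out = mutate_residue(ala, "A", 1, "to_ala")
        assert [(a.name, a.coords) for a in out.atoms] == [
            (a.name, a.coords) for a in ala.atoms
        ]

    def test_silence_charge_drops_net_by_one(self):
        lys = assign_charges(
            ChargedStructure(
                [make_atom(1, "CA", "LYS"), make_atom(2, "NZ", "LYS", coords=(3, 0, 0), element="N")]
            ),
            load_charge_model("formal"),
        )
        before = lys.net_charge
        after = mutate_residue(lys, "A", 1, "silence_charge").net_charge
        assert before - after == pytest.approx(1.0)

    def test_charge_swap_places_charge_on_outermost(self):
        s = self._asn_structure()
        swapped = mutate_residue(s, "A", 1, "charge_swap")
        by_name = {a.name: a.partial_charge for a in swapped.atoms}
        assert by_name["ND2"] == 1.0  # farthest retained sidechain atom from CA
        assert by_name["CB"] == 0.0

    def test_missing_residue_raises(self):
        with pytest.raises(ResidueNotFoundError):
            mutate_residue(self._asn_structure(), "A", 99, "to_ala")


def test_pdb_round_trip(specific_structure, tmp_path):
    """Write + re-read reproduces atom count, names and coordinates to 1e-3 Å."""
    path = tmp_path / "rt.pdb"
    write_pdb(specific_structure, path)
    back = read_structure(path)
    assert len(back) == len(specific_structure)
    for a, b in zip(specific_structure.atoms, back.atoms):
        assert a.name == b.name
        assert a.residue_name == b.residue_name
        assert np.allclose(a.coords, b.coords, atol=1e-3)
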