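import numpy as np
import pytest

from gagsite import (
    Atom,
    ChargedStructure,
    Locus,
    all_locus_potentials,
    assign_charges,
    load_charge_model,
    make_structure,
    SiteSpec,
)


def make_atom(
    serial,
    name="X",
    resname="GLY",
    resnum=1,
    chain="A",
    coords=(0.0, 0.0, 0.0),
    charge=0.0,
    element=None,
    **kw,
):
    return Atom(
        serial=serial,
        name=name,
        element=element or name[0],
        residue_name=resname,
        residue_number=resnum,
        insertion_code=kw.get("insertion_code", ""),
        chain_id=chain,
        coords=tuple(float(c) for c in coords),
        partial_charge=charge,
        alt_loc=kw.get("alt_loc", ""),
        het=kw.get("het", False),
    )


def random_charged_structure(seed, n_residues=15, atoms_per_residue=3, box=20.0):
    """Random point-charge structure for oracle cross-checks."""
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 0
    for res in range(1, n_residues + 1):
        for k in range(atoms_per_residue):
            serial += 1
            atoms.append(
                make_atom(
                    serial,
                    name=f"X{k}",
                    resname="UNK",
                    resnum=res,
                    coords=rng.uniform(-box, box, 3),
                    charge=float(rng.uniform(-1, 1)),
                    element="C",
                )
            )
    return ChargedStructure(atoms, charge_model="random", source_id=f"random-{seed}")


def loci_of(s, per_residue=1):
    """Treat the first atom of each residue as a locus (synthetic convention)."""
    out = []
    for idxs in s.residues().values():
        for i in idxs[:per_residue]:
            out.append(Locus.for_atom(s.atoms[i], "neutral_donor"))
    return out


@pytest.fixture(scope="session")
def specific_structure():
    s = make_structure(SiteSpec(kind="specific", seed=11))
    return assign_charges(s, load_charge_model("formal"))


@pytest.fixture(scope="session")
def nonspecific_structure():
    s = make_structure(SiteSpec(kind="nonspecific", seed=11))
    return assign_charges(s, load_charge_model("formal"))


@pytest.fixture(scope="session")
def specific_table(specific_structure):
    return all_locus_potentials(specific_structure, "neutral_donor")


@pytest.fixture(scope="session")
def nonspecific_table(nonspecific_structure):
    return all_locus_potentials(nonspecific_structure, "neutral_donor")


TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  GLY A   1       0.000   0.000   9.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   9.000  1.00  0.00           C
ENDMDL
END
"""

MESSY_PDB = """\
ATOM      1  N   ASN A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ASN A   1       1.400   0.000   0.000  1.00  0.00           C
ATOM      3  ND2AASN A   1       2.100   1.100   0.000  0.60  0.00           N
ATOM      4  ND2BASN A   1       2.200   1.200   0.100  0.40  0.00           N
ATOM      5  H   ASN A   1       0.500   0.900   0.000  1.00  0.00           H
ATOM      6  CA  GLY B   2       8.000   0.000   0.000  1.00  0.00           C
HETATM    7  C1  LIG B  90      12.000   0.000   0.000  1.00  0.00           C
HETATM    8  O   HOH B  91      15.000   0.000   0.000  1.00  0.00           O
HETATM    9  O   HOH B  92      16.000   0.000   0.000  1.00  0.00           O
END
"""


@pytest.fixture()
def two_model_pdb(tmp_path):
    p = tmp_path / "two_model.pdb"
    p.write_text(TWO_MODEL_PDB)
    return p


@pytest.fixture()
def messy_pdb(tmp_path):
    p = tmp_path / "messy.pdb"
    p.write_text(MESSY_PDB)
    return p
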