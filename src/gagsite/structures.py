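"""Protein structures as flat tables of point charges.

Everything downstream of this module works on a :class:`ChargedStructure`: an
ordered list of heavy atoms with coordinates in Å and partial charges in
elementary-charge units. Structures are read from standard PDB files
(Biopython does the parsing), cleaned of waters / heteroatoms / alternate
conformers, and charged from residue templates. Crystal structures carry no
hydrogens, so all charge models here are heavy-atom templates with hydrogen
charges folded into the parent heavy atom; no protonation engine is involved.

Donor *loci* — the points where electrostatic potential is evaluated — come in
two classes:

``basic_donor``
    terminal sidechain nitrogens of Arg (NE, NH1, NH2) and Lys (NZ);
``neutral_donor``
    sidechain hydrogen-bond donors of uncharged residues. The strict catalog
    is Asn ND2 and Gln NE2; the extended (default) catalog adds Ser OG,
    Thr OG1, Tyr OH, Trp NE1 and His ND1/NE2 (His only while modelled
    neutral).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser

__all__ = [
    "Atom",
    "ChargedStructure",
    "Locus",
    "ChargeModel",
    "StructureError",
    "EmptySelectionError",
    "UnknownResidueError",
    "ResidueNotFoundError",
    "read_structure",
    "clean_structure",
    "assign_charges",
    "identify_loci",
    "mutate_residue",
    "write_pdb",
    "load_charge_model",
    "BASIC_DONOR_CATALOG",
    "NEUTRAL_DONOR_CATALOG_STRICT",
    "NEUTRAL_DONOR_CATALOG_EXTENDED",
    "FORMAL_CHARGES",
]


class StructureError(Exception):
    """Base error for structure handling."""


class EmptySelectionError(StructureError):
    """A model/chain selection matched no atoms."""


class UnknownResidueError(StructureError):
    """A residue has no template in the charge model (strict mode)."""


class ResidueNotFoundError(StructureError):
    """A mutation target does not exist in the structure."""


WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: formal charge of each residue type under the default (neutral-His) model
FORMAL_CHARGES: Mapping[str, int] = {
    "ARG": +1,
    "LYS": +1,
    "ASP": -1,
    "GLU": -1,
}

BASIC_DONOR_CATALOG: Mapping[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
}

NEUTRAL_DONOR_CATALOG_STRICT: Mapping[str, tuple[str, ...]] = {
    "ASN": ("ND2",),
    "GLN": ("NE2",),
}

NEUTRAL_DONOR_CATALOG_EXTENDED: Mapping[str, tuple[str, ...]] = {
    **NEUTRAL_DONOR_CATALOG_STRICT,
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "TRP": ("NE1",),
    "HIS": ("ND1", "NE2"),
}

#: atoms retained by an alanine substitution
_ALA_BACKBONE = frozenset({"N", "CA", "C", "O", "OXT", "CB"})


@dataclass
class Atom:
    """One heavy atom: identity, position (Å) and partial charge (e)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    coords: tuple[float, float, float]
    partial_charge: float = 0.0
    alt_loc: str = ""
    het: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom {self.serial}")
        if not np.isfinite(self.partial_charge):
            raise StructureError(f"non-finite charge for atom {self.serial}")
        self.residue_name = self.residue_name.upper()

    @property
    def key(self) -> tuple[str, int, str, str, str]:
        """Unique identity (chain, resnum, icode, atom name, altloc)."""
        return (
            self.chain_id,
            self.residue_number,
            self.insertion_code,
            self.name,
            self.alt_loc,
        )

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES


@dataclass
class ChargedStructure:
    """An ordered collection of atoms plus its charge-model provenance."""

    atoms: list[Atom]
    charge_model: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            if a.key in seen:
                raise StructureError(f"duplicate atom identity {a.key}")
            seen.add(a.key)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> float:
        return float(sum(a.partial_charge for a in self.atoms))

    def coordinates(self) -> np.ndarray:
        """(N, 3) float array of positions in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def index_of(self, atom_ref: tuple) -> int:
        """Index of the atom whose :attr:`Atom.key` starts with ``atom_ref``.

        ``atom_ref`` may omit the trailing altloc element.
        """
        n = len(atom_ref)
        for i, a in enumerate(self.atoms):
            if a.key[:n] == tuple(atom_ref):
                return i
        raise ResidueNotFoundError(f"no atom matching {atom_ref!r}")

    def residue_atoms(self, residue_key: tuple[str, int, str]) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.residue_key == residue_key]

    def residues(self) -> dict[tuple[str, int, str], list[int]]:
        """Atom indices grouped per residue, in first-appearance order."""
        out: dict[tuple[str, int, str], list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def copy(self) -> "ChargedStructure":
        return ChargedStructure(
            atoms=[replace(a) for a in self.atoms],
            charge_model=self.charge_model,
            source_id=self.source_id,
        )


@dataclass(frozen=True)
class Locus:
    """A donor atom at which potential is evaluated."""

    atom_ref: tuple[str, int, str, str]  # chain, resnum, icode, atom name
    locus_class: str  # "basic_donor" | "neutral_donor"
    label: str

    @staticmethod
    def for_atom(atom: Atom, locus_class: str) -> "Locus":
        return Locus(
            atom_ref=(atom.chain_id, atom.residue_number, atom.insertion_code, atom.name),
            locus_class=locus_class,
            label=f"{atom.chain_id}:{atom.residue_name} {atom.residue_number}{atom.insertion_code.strip()}:{atom.name}",
        )


@dataclass
class ChargeModel:
    """Residue-template partial charges (heavy atoms, hydrogens folded in)."""

    name: str
    residue_templates: Mapping[str, Mapping[str, float]]
    default_charge: float = 0.0

    def validate(self, formal: Mapping[str, int] = FORMAL_CHARGES, tol: float = 0.01) -> None:
        """Check each template sums to the residue's formal charge."""
        for res, tmpl in self.residue_templates.items():
            expected = formal.get(res, 0)
            total = sum(tmpl.values())
            if abs(total - expected) > tol:
                raise StructureError(
                    f"{self.name}: template {res} sums to {total:.3f}, expected {expected}"
                )


def _formal_model(his_charged: bool = False) -> ChargeModel:
    templates: dict[str, dict[str, float]] = {
        "ARG": {"NH1": 0.5, "NH2": 0.5},
        "LYS": {"NZ": 1.0},
        "ASP": {"OD1": -0.5, "OD2": -0.5},
        "GLU": {"OE1": -0.5, "OE2": -0.5},
    }
    if his_charged:
        templates["HIS"] = {"ND1": 0.5, "NE2": 0.5}
    name = "formal+his" if his_charged else "formal"
    return ChargeModel(name=name, residue_templates=templates)


def _read_template_tsv(path_or_text: str) -> dict[str, dict[str, float]]:
    templates: dict[str, dict[str, float]] = {}
    for line in path_or_text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, q = line.split("\t")
        templates.setdefault(res.upper(), {})[atom] = float(q)
    return templates


def load_charge_model(name: str, his_charged: bool = False) -> ChargeModel:
    """Load a shipped charge model: ``formal``, ``mmff94-like`` or ``charmm-like``.

    ``his_charged`` applies only to the formal model (doubly protonated His,
    +0.5 on each ring nitrogen); the template models keep His neutral.
    """
    if name == "formal":
        model = _formal_model(his_charged=his_charged)
    elif name in ("mmff94-like", "charmm-like"):
        fname = "charges_mmff94_like.tsv" if name == "mmff94-like" else "charges_charmm_like.tsv"
        text = resources.files("gagsite.data").joinpath(fname).read_text()
        model = ChargeModel(name=name, residue_templates=_read_template_tsv(text))
    else:
        raise ValueError(f"unknown charge model {name!r}")
    formal = dict(FORMAL_CHARGES)
    if his_charged:
        formal["HIS"] = +1
    model.validate(formal)
    return model


# ---------------------------------------------------------------------------
# reading / cleaning


def read_structure(
    path: str | Path,
    model_index: int = 1,
    chains: Iterable[str] | None = None,
) -> ChargedStructure:
    """Read a PDB file into an (uncharged) :class:`ChargedStructure`.

    ``model_index`` is the 1-based ordinal of the MODEL block to keep;
    ``chains`` restricts to the given chain identifiers. Atoms appear in file
    order and all partial charges are zero.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        bio = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Bio.PDB raises assorted exception types
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    models = list(bio.get_models())
    if not models:
        raise EmptySelectionError(f"{path}: no models")
    if not 1 <= model_index <= len(models):
        raise EmptySelectionError(
            f"{path}: model_index {model_index} outside 1..{len(models)}"
        )
    model = models[model_index - 1]

    wanted = set(chains) if chains is not None else None
    atoms: list[Atom] = []
    serial = 0
    for chain in model:
        if wanted is not None and chain.id not in wanted:
            continue
        for residue in chain:
            hetfield, resnum, icode = residue.id
            het = hetfield.strip() != ""
            for bio_atom in residue.get_unpacked_list():
                serial += 1
                # PDB coordinates carry 3 decimals; rounding removes float32 noise
                x, y, z = (round(float(v), 3) for v in bio_atom.coord)
                atoms.append(
                    Atom(
                        serial=bio_atom.serial_number or serial,
                        name=bio_atom.get_name(),
                        element=(bio_atom.element or "").strip() or bio_atom.get_name()[0],
                        residue_name=residue.get_resname().strip(),
                        residue_number=resnum,
                        insertion_code=icode.strip(),
                        chain_id=chain.id,
                        coords=(x, y, z),
                        alt_loc=bio_atom.get_altloc().strip(),
                        het=het,
                    )
                )
    if not atoms:
        raise EmptySelectionError(f"{path}: selection matched no atoms")
    return ChargedStructure(atoms=atoms, source_id=path.stem)


def clean_structure(
    s: ChargedStructure,
    keep_het: bool = False,
    keep_hydrogens: bool = False,
) -> ChargedStructure:
    """Drop waters, heteroatoms, hydrogens and alternate conformers.

    Waters are always removed. For alt-loc duplicates of the same atom
    identity, the first-listed conformer wins (a deterministic tie-break).
    """
    kept: list[Atom] = []
    seen_no_alt: set[tuple] = set()
    for a in s.atoms:
        if a.is_water:
            continue
        if a.het and not keep_het:
            continue
        if a.is_hydrogen and not keep_hydrogens:
            continue
        ident = a.key[:4]  # identity ignoring altloc
        if ident in seen_no_alt:
            continue
        seen_no_alt.add(ident)
        kept.append(replace(a))
    return ChargedStructure(kept, charge_model=s.charge_model, source_id=s.source_id)


# ---------------------------------------------------------------------------
# charges, loci, mutation


def assign_charges(
    s: ChargedStructure,
    model: ChargeModel,
    strict: bool = False,
) -> ChargedStructure:
    """Return a copy of ``s`` with template charges applied.

    Atoms missing from their residue's template get ``model.default_charge``;
    residues with no template at all raise in ``strict`` mode and warn
    otherwise. Idempotent for a given model.
    """
    out = s.copy()
    warned: set[str] = set()
    for a in out.atoms:
        tmpl = model.residue_templates.get(a.residue_name)
        if tmpl is None:
            if a.residue_name not in _TEMPLATE_FREE_OK and model.name not in ("formal", "formal+his"):
                if strict:
                    raise UnknownResidueError(
                        f"no {model.name} template for residue {a.residue_name}"
                    )
                if a.residue_name not in warned:
                    warned.add(a.residue_name)
                    warnings.warn(
                        f"no {model.name} template for {a.residue_name}; "
                        f"using default charge {model.default_charge}",
                        stacklevel=2,
                    )
            a.partial_charge = model.default_charge
        else:
            a.partial_charge = tmpl.get(a.name, model.default_charge)
    out.charge_model = model.name
    return out


#: residues legitimately absent from the sparse formal templates
_TEMPLATE_FREE_OK = frozenset(
    {
        "ALA", "ASN", "CYS", "GLN", "GLY", "HIS", "ILE", "LEU", "MET",
        "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)


def _residue_net_charge(s: ChargedStructure, idxs: Sequence[int]) -> float:
    return float(sum(s.atoms[i].partial_charge for i in idxs))


def identify_loci(
    s: ChargedStructure,
    locus_class: str,
    catalog: Mapping[str, tuple[str, ...]] | None = None,
) -> list[Locus]:
    """List donor loci of one class, sorted by chain then residue number.

    For ``neutral_donor`` the default is the extended catalog; His ring
    nitrogens count only while the residue's model charge is neutral
    (|net| < 0.25 e). Pass ``catalog=NEUTRAL_DONOR_CATALOG_STRICT`` for the
    minimal Asn/Gln-only reading.
    """
    if locus_class == "basic_donor":
        cat = catalog if catalog is not None else BASIC_DONOR_CATALOG
    elif locus_class == "neutral_donor":
        cat = catalog if catalog is not None else NEUTRAL_DONOR_CATALOG_EXTENDED
    else:
        raise ValueError(f"unknown locus class {locus_class!r}")

    loci: list[Locus] = []
    for res_key, idxs in s.residues().items():
        res_name = s.atoms[idxs[0]].residue_name
        atom_names = cat.get(res_name)
        if not atom_names:
            continue
        if (
            locus_class == "neutral_donor"
            and res_name == "HIS"
            and abs(_residue_net_charge(s, idxs)) >= 0.25
        ):
            continue
        by_name = {s.atoms[i].name: s.atoms[i] for i in idxs}
        for name in atom_names:
            if name in by_name:
                loci.append(Locus.for_atom(by_name[name], locus_class))
    loci.sort(key=lambda l: (l.atom_ref[0], l.atom_ref[1], l.atom_ref[2], l.atom_ref[3]))
    return loci


def mutate_residue(
    s: ChargedStructure,
    chain: str,
    residue_number: int,
    mode: str,
    insertion_code: str = "",
    swap_charge: float = +1.0,
) -> ChargedStructure:
    """Apply an in-silico point mutation and return the modified copy.

    Modes:

    ``to_ala``
        remove sidechain atoms beyond CB and rename the residue ALA;
    ``silence_charge``
        zero all sidechain partial charges (backbone untouched);
    ``charge_swap``
        zero sidechain charges, then place ``swap_charge`` on the retained
        sidechain atom farthest from CA — a geometry-free stand-in for an
        Arg/Lys substitution.
    """
    res_key = (chain, residue_number, insertion_code)
    idxs = s.residue_atoms(res_key)
    if not idxs:
        raise ResidueNotFoundError(f"no residue {res_key} in structure")
    backbone = frozenset({"N", "CA", "C", "O", "OXT"})

    out = s.copy()
    if mode == "to_ala":
        keep = [
            a
            for a in out.atoms
            if a.residue_key != res_key or a.name in _ALA_BACKBONE
        ]
        for a in keep:
            if a.residue_key == res_key:
                a.residue_name = "ALA"
        return ChargedStructure(keep, charge_model=out.charge_model, source_id=out.source_id)

    if mode == "silence_charge":
        for i in out.residue_atoms(res_key):
            if out.atoms[i].name not in backbone:
                out.atoms[i].partial_charge = 0.0
        return out

    if mode == "charge_swap":
        side = [i for i in out.residue_atoms(res_key) if out.atoms[i].name not in backbone]
        if not side:
            raise StructureError(f"residue {res_key} has no sidechain atoms to swap")
        for i in side:
            out.atoms[i].partial_charge = 0.0
        try:
            ca = out.atoms[out.index_of((chain, residue_number, insertion_code, "CA"))]
            origin = np.asarray(ca.coords)
        except ResidueNotFoundError:
            origin = np.mean([out.atoms[i].coords for i in side], axis=0)
        outermost = max(
            side, key=lambda i: float(np.linalg.norm(np.asarray(out.atoms[i].coords) - origin))
        )
        out.atoms[outermost].partial_charge = swap_charge
        return out

    raise ValueError(f"unknown mutation mode {mode!r}")


# ---------------------------------------------------------------------------
# writing


def write_pdb(s: ChargedStructure, path: str | Path) -> None:
    """Write ATOM/HETATM records (fixed-width PDB format), TER per chain."""
    lines: list[str] = []
    serial = 0
    prev_chain: str | None = None
    last_atom: Atom | None = None

    def ter(atom: Atom, serial: int) -> str:
        return (
            f"TER   {serial:5d}      {atom.residue_name:>3s} {atom.chain_id:1s}"
            f"{atom.residue_number:4d}{atom.insertion_code or ' ':1s}"
        )

    for a in s.atoms:
        if prev_chain is not None and a.chain_id != prev_chain and last_atom is not None:
            serial += 1
            lines.append(ter(last_atom, serial))
        serial += 1
        record = "HETATM" if a.het else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.coords
        lines.append(
            f"{record}{serial:5d} {name:<4s}{a.alt_loc or ' ':1s}{a.residue_name:>3s} "
            f"{a.chain_id:1s}{a.residue_number:4d}{a.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element.upper():>2s}"
        )
        prev_chain = a.chain_id
        last_atom = a
    if last_atom is not None:
        serial += 1
        lines.append(ter(last_atom, serial))
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
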