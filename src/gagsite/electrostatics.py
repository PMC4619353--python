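"""Multi-body Coulomb potential at donor loci.

The potential manifested at a locus is the screened Coulomb sum over every
other atom of the structure,

    G_ES = s · Σ_j k q_j / (ε(r_j) · r_j),   k = 332.0636 kcal·Å/(mol·e²),

with the locus's own residue excluded by default. The probe sign ``s``
defaults to −1 so that an electropositive environment — the kind that attracts
an anionic glycosaminoglycan — yields a *negative* ("high") G_ES, matching the
plotting convention where the largest markers are the most binding-conducive
loci. The dielectric ε is either a uniform constant (default 4) or the
distance-dependent form ε(r) = ε·r.

Restricted to neutral-donor loci the resulting table is the quantity referred
to throughout as G_GAG-binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import ChargedStructure, Locus, identify_loci

__all__ = [
    "COULOMB_CONSTANT",
    "DielectricModel",
    "PotentialTable",
    "CoincidentAtomError",
    "locus_potential",
    "all_locus_potentials",
]

#: Coulomb constant in kcal·Å/(mol·e²)
COULOMB_CONSTANT = 332.0636


class CoincidentAtomError(ValueError):
    """Two atoms closer than 1e-6 Å: the 1/r sum is undefined."""


@dataclass(frozen=True)
class DielectricModel:
    """Dielectric screening: ``uniform`` ε or ``distance_dependent`` ε(r)=ε·r."""

    kind: str = "uniform"
    epsilon: float = 4.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "distance_dependent"):
            raise ValueError(f"unknown dielectric kind {self.kind!r}")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    def screening(self, r: np.ndarray) -> np.ndarray:
        """ε(r)·r — the full denominator of the screened Coulomb term."""
        r = np.asarray(r, dtype=float)
        if self.kind == "uniform":
            return self.epsilon * r
        return self.epsilon * r * r

    def label(self) -> str:
        return f"{self.kind}:{self.epsilon:g}"


@dataclass
class PotentialTable:
    """Per-locus G_ES (kcal/mol) for one structure / dielectric / charge model."""

    entries: list[tuple[Locus, float]]
    structure_id: str = ""
    dielectric: DielectricModel = field(default_factory=DielectricModel)
    charge_model: str = ""
    probe_sign: int = -1

    def __post_init__(self) -> None:
        if any(not np.isfinite(g) for _, g in self.entries):
            raise ValueError("non-finite G_ES in potential table")

    def __len__(self) -> int:
        return len(self.entries)

    def values(self) -> np.ndarray:
        return np.array([g for _, g in self.entries], dtype=float)

    def loci(self) -> list[Locus]:
        return [l for l, _ in self.entries]

    def per_residue_min(self) -> "PotentialTable":
        """Aggregate to one entry per residue: the most negative donor atom."""
        best: dict[tuple, tuple[Locus, float]] = {}
        for locus, g in self.entries:
            rkey = locus.atom_ref[:3]
            if rkey not in best or g < best[rkey][1]:
                best[rkey] = (locus, g)
        return PotentialTable(
            entries=list(best.values()),
            structure_id=self.structure_id,
            dielectric=self.dielectric,
            charge_model=self.charge_model,
            probe_sign=self.probe_sign,
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for locus, g in self.entries:
            chain, resnum, icode, atom = locus.atom_ref
            resname = locus.label.split(":")[1].split(" ")[0]
            rows.append(
                {
                    "structure_id": self.structure_id,
                    "chain": chain,
                    "residue_name": resname,
                    "residue_number": resnum,
                    "atom_name": atom,
                    "locus_class": locus.locus_class,
                    "G_ES_kcal_mol": g,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "structure_id", "chain", "residue_name", "residue_number",
                "atom_name", "locus_class", "G_ES_kcal_mol",
            ],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _exclusion_mask(
    s: ChargedStructure, locus_index: int, exclusion: str
) -> np.ndarray:
    """Boolean mask of atoms *included* in the sum."""
    mask = np.ones(len(s), dtype=bool)
    if exclusion == "residue":
        res_key = s.atoms[locus_index].residue_key
        for i, a in enumerate(s.atoms):
            if a.residue_key == res_key:
                mask[i] = False
    elif exclusion == "self":
        mask[locus_index] = False
    else:
        raise ValueError(f"unknown exclusion mode {exclusion!r}")
    return mask


def locus_potential(
    s: ChargedStructure,
    locus: Locus,
    dielectric: DielectricModel | None = None,
    probe_sign: int = -1,
    exclusion: str = "residue",
) -> float:
    """Coulomb potential (kcal/mol) at one locus from the rest of the structure.

    ``exclusion`` is ``"residue"`` (default: skip every atom of the locus's
    own residue, avoiding self-polarisation artifacts) or ``"self"`` (skip
    only the locus atom).
    """
    d = dielectric or DielectricModel()
    idx = s.index_of(locus.atom_ref)
    mask = _exclusion_mask(s, idx, exclusion)
    if not mask.any():
        return 0.0
    coords = s.coordinates()
    r = np.linalg.norm(coords[mask] - coords[idx], axis=1)
    if np.any(r < 1e-6):
        raise CoincidentAtomError(
            f"atom coincident with locus {locus.label} (r < 1e-6 Å)"
        )
    q = s.charges()[mask]
    return float(probe_sign * COULOMB_CONSTANT * np.sum(q / d.screening(r)))


def all_locus_potentials(
    s: ChargedStructure,
    locus_class: str = "neutral_donor",
    dielectric: DielectricModel | None = None,
    probe_sign: int = -1,
    exclusion: str = "residue",
    catalog=None,
    loci: Sequence[Locus] | None = None,
) -> PotentialTable:
    """Evaluate :func:`locus_potential` at every locus of one class."""
    d = dielectric or DielectricModel()
    if loci is None:
        loci = identify_loci(s, locus_class, catalog=catalog)
    entries = [
        (locus, locus_potential(s, locus, d, probe_sign=probe_sign, exclusion=exclusion))
        for locus in loci
    ]
    return PotentialTable(
        entries=entries,
        structure_id=s.source_id,
        dielectric=d,
        charge_model=s.charge_model,
        probe_sign=probe_sign,
    )
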