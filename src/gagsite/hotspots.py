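"""Hot-spot statistics and specificity classification.

The discriminating signal for a specific GAG-binding site is a neutral
hydrogen-bond donor whose potential sits in the extreme negative tail of the
structure-wide G_GAG-binding distribution — a "hot spot". A structure with at
least one hot spot is called *specific*; one whose donor potentials are
diffuse (no extreme tail) is *nonspecific*. The tail criterion is a z-score
threshold (default z ≤ −2), a declared artifact-level choice; Shapiro-Wilk
normality of the distribution is reported as supporting evidence, not used as
a gate. Each hot spot is annotated with the nearby basic residues (terminal
sidechain nitrogens of Arg/Lys within a cutoff) — the local constellation
that creates the potential bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .electrostatics import PotentialTable
from .structures import BASIC_DONOR_CATALOG, ChargedStructure, Locus

__all__ = [
    "DistributionSummary",
    "HotSpot",
    "SpecificityCall",
    "InsufficientDataError",
    "NoVarianceError",
    "summarize_distribution",
    "find_hotspots",
    "classify_specificity",
    "violin_export",
]


class InsufficientDataError(ValueError):
    """Fewer than three loci: moments/normality are not assessable."""


class NoVarianceError(ValueError):
    """Zero spread: z-scores are undefined."""


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    mean: float
    sd: float
    min: float
    skewness: float
    normality_p: float  # NaN when not assessable (zero variance)

    @property
    def normality_applicable(self) -> bool:
        return np.isfinite(self.normality_p)


@dataclass(frozen=True)
class HotSpot:
    locus: Locus
    G_ES: float
    z_score: float
    neighbors: tuple[tuple[str, float], ...]  # (basic residue label, min distance Å)


@dataclass
class SpecificityCall:
    verdict: str  # "specific" | "nonspecific"
    summary: DistributionSummary
    hotspots: list[HotSpot]
    threshold_z: float
    structure_id: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "structure_id": self.structure_id,
                    "locus": h.locus.label,
                    "G_ES_kcal_mol": h.G_ES,
                    "z_score": h.z_score,
                    "n_basic_neighbors": len(h.neighbors),
                    "basic_neighbors": "; ".join(
                        f"{lab} ({d:.1f} Å)" for lab, d in h.neighbors
                    ),
                }
                for h in self.hotspots
            ],
            columns=[
                "structure_id", "locus", "G_ES_kcal_mol", "z_score",
                "n_basic_neighbors", "basic_neighbors",
            ],
        )

    def report_text(self) -> str:
        s = self.summary
        lines = [
            f"structure: {self.structure_id}",
            f"verdict: {self.verdict}",
            f"loci: n={s.n}  mean={s.mean:.3f}  sd={s.sd:.3f}  min={s.min:.3f} kcal/mol",
            f"skewness: {s.skewness:.3f}",
            (
                f"Shapiro-Wilk normality p: {s.normality_p:.4f}"
                if s.normality_applicable
                else "Shapiro-Wilk normality p: not applicable (zero variance)"
            ),
            f"hot-spot criterion: z <= -{self.threshold_z:g}",
            f"hot spots: {len(self.hotspots)}",
        ]
        for h in self.hotspots:
            lines.append(f"  {h.locus.label}  G_ES={h.G_ES:.3f}  z={h.z_score:.2f}")
            for lab, d in h.neighbors:
                lines.append(f"    near {lab} at {d:.1f} Å")
        return "\n".join(lines)

    def write(self, tsv_path: str | Path, text_path: str | Path | None = None) -> None:
        self.to_dataframe().to_csv(tsv_path, sep="\t", index=False)
        if text_path is not None:
            Path(text_path).write_text(self.report_text() + "\n")


def summarize_distribution(table: PotentialTable) -> DistributionSummary:
    """Moments + Shapiro-Wilk normality of the per-locus potentials."""
    values = table.values()
    if len(values) < 3:
        raise InsufficientDataError(
            f"need >= 3 loci for a distribution summary, got {len(values)}"
        )
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        skew, p = 0.0, float("nan")
    else:
        skew = float(stats.skew(values))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.shapiro(values).pvalue)
    return DistributionSummary(
        n=len(values),
        mean=float(values.mean()),
        sd=sd,
        min=float(values.min()),
        skewness=skew,
        normality_p=p,
    )


def _basic_neighbors(
    s: ChargedStructure, locus: Locus, cutoff: float
) -> tuple[tuple[str, float], ...]:
    """Arg/Lys residues with a terminal sidechain N within ``cutoff`` Å.

    Distance per residue is the minimum over its terminal nitrogens; sorted by
    distance.
    """
    center = np.asarray(s.atoms[s.index_of(locus.atom_ref)].coords)
    best: dict[tuple, tuple[str, float]] = {}
    for a in s.atoms:
        names = BASIC_DONOR_CATALOG.get(a.residue_name)
        if not names or a.name not in names:
            continue
        d = float(np.linalg.norm(np.asarray(a.coords) - center))
        if d > cutoff:
            continue
        label = f"{a.chain_id}:{a.residue_name} {a.residue_number}{a.insertion_code.strip()}"
        if a.residue_key not in best or d < best[a.residue_key][1]:
            best[a.residue_key] = (label, d)
    return tuple(sorted(best.values(), key=lambda t: t[1]))


def find_hotspots(
    table: PotentialTable,
    s: ChargedStructure,
    threshold_z: float = 2.0,
    neighbor_cutoff: float = 12.0,
) -> list[HotSpot]:
    """Loci whose z-score (G − mean)/sd is ≤ −threshold_z, with neighbors."""
    summary = summarize_distribution(table)
    if summary.sd == 0.0:
        raise NoVarianceError("all potentials identical: z-scores undefined")
    out = []
    for locus, g in table.entries:
        z = (g - summary.mean) / summary.sd
        if z <= -threshold_z:
            out.append(
                HotSpot(
                    locus=locus,
                    G_ES=g,
                    z_score=z,
                    neighbors=_basic_neighbors(s, locus, neighbor_cutoff),
                )
            )
    out.sort(key=lambda h: h.z_score)
    return out


def classify_specificity(
    table: PotentialTable,
    s: ChargedStructure,
    threshold_z: float = 2.0,
    neighbor_cutoff: float = 12.0,
) -> SpecificityCall:
    """Specific iff at least one hot spot exists; full report attached."""
    hotspots = find_hotspots(table, s, threshold_z, neighbor_cutoff)
    return SpecificityCall(
        verdict="specific" if hotspots else "nonspecific",
        summary=summarize_distribution(table),
        hotspots=hotspots,
        threshold_z=threshold_z,
        structure_id=table.structure_id or s.source_id,
    )


def violin_export(tables: Iterable[PotentialTable]) -> pd.DataFrame:
    """Long-format (structure_id, locus, G_ES) rows for violin/density plots."""
    rows = []
    for t in tables:
        for locus, g in t.entries:
            rows.append(
                {"structure_id": t.structure_id, "locus": locus.label, "G_ES_kcal_mol": g}
            )
    return pd.DataFrame(rows, columns=["structure_id", "locus", "G_ES_kcal_mol"])
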