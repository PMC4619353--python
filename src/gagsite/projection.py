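"""2D-Surface-Energy (2DSE) plot construction.

A locus at (x, y, z) is projected onto the plane as (ρ, z) with
ρ = (x² + y²)^½ — its distance from the origin in the x–y plane. Marker areas
encode energy through the Boltzmann-style affinity ratio

    area = exp((G_ref − G) / RT),

capped so a single extreme hot spot cannot dominate the canvas. Because
K_d ratios relate to ΔΔG as K₂/K₁ = e^(ΔΔG/RT), the ratio of two marker
areas is exactly the affinity ratio the two loci would imply — making the
scatter a quantitative map of where an anionic ligand would rather sit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .electrostatics import PotentialTable
from .structures import ChargedStructure, Locus

__all__ = [
    "RT_298",
    "DEFAULT_CAP",
    "DSEPoint",
    "DSEPlotData",
    "EmptyPlotError",
    "project_point",
    "scale_marker",
    "build_2dse",
]

#: RT at 298 K in kcal/mol
RT_298 = 0.593

#: default area-factor cap (e⁵ ≈ 148): purely presentational
DEFAULT_CAP = math.e**5


class EmptyPlotError(ValueError):
    """A 2DSE plot cannot be built from an empty potential table."""


@dataclass(frozen=True)
class DSEPoint:
    locus: Locus
    rho: float
    z: float
    G_ES: float
    area_factor: float

    def __post_init__(self) -> None:
        if self.rho < 0 or not self.area_factor > 0:
            raise ValueError("invalid 2DSE point (rho < 0 or area_factor <= 0)")


@dataclass
class DSEPlotData:
    points: list[DSEPoint]
    reference_G: float
    RT: float = RT_298
    cap: float = DEFAULT_CAP
    structure_id: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus": p.locus.label,
                    "rho_A": p.rho,
                    "z_A": p.z,
                    "G_ES_kcal_mol": p.G_ES,
                    "area_factor": p.area_factor,
                }
                for p in self.points
            ],
            columns=["locus", "rho_A", "z_A", "G_ES_kcal_mol", "area_factor"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def plot(self, path: str | Path | None = None, base_area: float = 20.0, ax=None):
        """Render the scatter with marker area ∝ area_factor (matplotlib)."""
        import matplotlib

        if path is not None and ax is None:
            matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        rho = [p.rho for p in self.points]
        z = [p.z for p in self.points]
        area = [base_area * p.area_factor for p in self.points]
        g = [p.G_ES for p in self.points]
        sc = ax.scatter(rho, z, s=area, c=g, cmap="coolwarm_r", alpha=0.75, edgecolors="k", linewidths=0.3)
        ax.set_xlabel(r"$\rho = (x^2+y^2)^{1/2}$ (Å)")
        ax.set_ylabel("z (Å)")
        ax.set_title(f"2DSE plot: {self.structure_id}" if self.structure_id else "2DSE plot")
        plt.colorbar(sc, ax=ax, label=r"$G_{ES}$ (kcal/mol)")
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def project_point(coords: Sequence[float]) -> tuple[float, float]:
    """Project (x, y, z) to the (ρ, z) plane; ρ = (x²+y²)^½."""
    x, y, z = (float(v) for v in coords)
    return math.hypot(x, y), z


def scale_marker(
    G: float,
    reference_G: float,
    RT: float = RT_298,
    cap: float = DEFAULT_CAP,
) -> float:
    """Exponential marker-area factor: min(exp((G_ref − G)/RT), cap).

    Monotone non-increasing in G — a more negative (more binding-conducive)
    potential gives a larger marker.
    """
    if not RT > 0:
        raise ValueError("RT must be positive")
    return float(min(math.exp((reference_G - G) / RT), cap))


def build_2dse(
    s: ChargedStructure,
    table: PotentialTable,
    reference: str | float = "mean",
    RT: float = RT_298,
    cap: float = DEFAULT_CAP,
    origin: str = "raw",
) -> DSEPlotData:
    """Build 2DSE plot data from a structure and its potential table.

    ``reference`` sets the G that maps to area 1: ``"mean"`` (default),
    ``"least_negative"``, or an explicit kcal/mol value. ``origin`` is
    ``"raw"`` (deposited coordinates) or ``"centroid"`` (translate the
    structure centroid to the origin before projecting).
    """
    if len(table) == 0:
        raise EmptyPlotError("cannot build a 2DSE plot from an empty table")
    values = table.values()
    if reference == "mean":
        ref = float(values.mean())
    elif reference == "least_negative":
        ref = float(values.max())
    elif isinstance(reference, (int, float)):
        ref = float(reference)
    else:
        raise ValueError(f"unknown reference rule {reference!r}")

    if origin == "raw":
        shift = np.zeros(3)
    elif origin == "centroid":
        shift = s.coordinates().mean(axis=0)
    else:
        raise ValueError(f"unknown origin rule {origin!r}")

    points = []
    for locus, g in table.entries:
        atom = s.atoms[s.index_of(locus.atom_ref)]
        rho, z = project_point(np.asarray(atom.coords) - shift)
        points.append(
            DSEPoint(
                locus=locus,
                rho=rho,
                z=z,
                G_ES=g,
                area_factor=scale_marker(g, ref, RT=RT, cap=cap),
            )
        )
    return DSEPlotData(
        points=points,
        reference_G=ref,
        RT=RT,
        cap=cap,
        structure_id=table.structure_id,
    )
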