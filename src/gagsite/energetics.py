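"""Binding energetics: Kd → ΔΔG, ES/desolvation decomposition, mutant tables.

Observed binding free-energy differences come from dissociation constants via
ΔΔG_OBS = RT ln(Kd_mutant / Kd_wt). Complex energetics are decomposed into an
electrostatic interaction term (screened Coulomb cross-sum between the
partners, inner dielectric 2) and a desolvation term supplied by a pluggable
solver, each defined as complex-minus-separated-parts. The shipped
``born_surrogate`` solver is a generalized-Born-style model of this package's
own design: it honors the decomposition contract (zero in the separated
limit, desolvation penalty grows with burial, q² scaling) without reproducing
any particular grid Poisson-Boltzmann implementation's numbers.

The mutant-table analysis recomputes ΔΔG_OBS for every published variant and
runs the three cross-column regressions (ES vs OBS, DS vs OBS, ES vs DS),
applying an OLS fit when both series pass Shapiro-Wilk normality and falling
back to Spearman rank correlation otherwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .electrostatics import COULOMB_CONSTANT, CoincidentAtomError, DielectricModel
from .structures import ChargedStructure

__all__ = [
    "GAS_CONSTANT_KCAL",
    "MutantRecord",
    "EnergyDecomposition",
    "RegressionResult",
    "MutantTableReport",
    "ddg_from_kd",
    "coulomb_interaction_energy",
    "born_surrogate_desolvation",
    "decompose_interaction",
    "regression_with_normality_gate",
    "mutant_table_analysis",
]

#: gas constant in kcal/(mol·K)
GAS_CONSTANT_KCAL = 1.9872e-3

#: Born-surrogate parameters: base radius (Å), growth per buried neighbor (Å),
#: burial-counting cutoff (Å), inner/outer dielectric constants.
BORN_BASE_RADIUS = 2.0
BORN_RADIUS_PER_NEIGHBOR = 0.1
BURIAL_CUTOFF = 6.0
EPSILON_INNER = 2.0
EPSILON_OUTER = 80.0


@dataclass
class MutantRecord:
    """One published variant: energy components plus the measured Kd."""

    label: str
    dG_ES: float
    ddG_ES: float
    dG_DS: float
    ddG_DS: float
    Kd_nM: float
    ddG_OBS: float
    comparator: str = "Wt"

    def __post_init__(self) -> None:
        if not self.Kd_nM > 0:
            raise ValueError(f"{self.label}: Kd must be positive")


@dataclass(frozen=True)
class EnergyDecomposition:
    dG_ES: float
    dG_DS: float
    solver: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dG_ES) and np.isfinite(self.dG_DS)):
            raise ValueError("non-finite energy decomposition")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    method: str  # "pearson_ols" | "spearman"
    normality_p: float  # min of the two series' Shapiro-Wilk p-values


def ddg_from_kd(
    kd_variant: float, kd_reference: float, temperature: float = 298.0
) -> float:
    """ΔΔG_OBS = RT ln(Kd_variant / Kd_reference), in kcal/mol.

    Any common concentration unit works as long as both Kd share it.
    """
    if not (kd_variant > 0 and kd_reference > 0):
        raise ValueError("Kd values must be positive")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    return GAS_CONSTANT_KCAL * temperature * math.log(kd_variant / kd_reference)


def coulomb_interaction_energy(
    a: ChargedStructure,
    b: ChargedStructure,
    dielectric: DielectricModel | None = None,
) -> float:
    """Screened Coulomb cross-term Σᵢⱼ k qᵢqⱼ/(ε(r)·r) between two partners."""
    d = dielectric or DielectricModel(epsilon=EPSILON_INNER)
    qa, qb = a.charges(), b.charges()
    if len(qa) == 0 or len(qb) == 0 or (not qa.any()) or (not qb.any()):
        return 0.0
    r = cdist(a.coordinates(), b.coordinates())
    if np.any(r < 1e-6):
        raise CoincidentAtomError("coincident atoms across partners")
    return float(COULOMB_CONSTANT * np.sum(np.outer(qa, qb) / d.screening(r)))


def _burial_counts(coords: np.ndarray, others: np.ndarray | None) -> np.ndarray:
    """Per-atom count of non-self heavy atoms within the burial cutoff."""
    n = len(coords)
    counts = np.zeros(n)
    if n > 1:
        r = cdist(coords, coords)
        counts += (r < BURIAL_CUTOFF).sum(axis=1) - 1  # minus self
    if others is not None and len(others):
        counts += (cdist(coords, others) < BURIAL_CUTOFF).sum(axis=1)
    return counts


def born_surrogate_desolvation(
    s: ChargedStructure,
    partner: ChargedStructure | None,
    epsilon_inner: float = EPSILON_INNER,
    epsilon_outer: float = EPSILON_OUTER,
) -> float:
    """Desolvation penalty (kcal/mol) of ``s`` upon binding ``partner``.

    Each charged atom carries an effective Born radius that grows linearly
    with burial, R(b) = R₀ + k·b, where b counts non-self heavy atoms within
    the cutoff (partner atoms included in the complex state). The penalty is

        Σ −(k_C/2)·q²·(1/ε_out − 1/ε_in)·(1/R_alone − 1/R_complex),

    which is ≥ 0 whenever binding only adds burial, and scales as q².
    """
    if partner is None or len(partner) == 0:
        return 0.0
    coords = s.coordinates()
    q = s.charges()
    b_alone = _burial_counts(coords, None)
    b_complex = _burial_counts(coords, partner.coordinates())
    r_alone = BORN_BASE_RADIUS + BORN_RADIUS_PER_NEIGHBOR * b_alone
    r_complex = BORN_BASE_RADIUS + BORN_RADIUS_PER_NEIGHBOR * b_complex
    deps = 1.0 / epsilon_outer - 1.0 / epsilon_inner
    terms = -(COULOMB_CONSTANT / 2.0) * q**2 * deps * (1.0 / r_alone - 1.0 / r_complex)
    return float(terms.sum())


def decompose_interaction(
    complex_protein: ChargedStructure,
    complex_ligand: ChargedStructure,
    solver: str = "born_surrogate",
    dielectric: DielectricModel | None = None,
) -> EnergyDecomposition:
    """ΔG_ES + ΔG_DS for a two-partner complex, complex minus parts.

    The electrostatic term is the inter-partner Coulomb cross-sum (the
    intra-partner sums cancel in complex-minus-parts for rigid partners). The
    desolvation term sums each partner's burial penalty. Solvers: ``"null"``
    (ΔG_DS = 0) and ``"born_surrogate"``.
    """
    d = dielectric or DielectricModel(epsilon=EPSILON_INNER)
    dg_es = coulomb_interaction_energy(complex_protein, complex_ligand, d)
    if solver == "null":
        dg_ds = 0.0
    elif solver == "born_surrogate":
        dg_ds = born_surrogate_desolvation(
            complex_protein, complex_ligand
        ) + born_surrogate_desolvation(complex_ligand, complex_protein)
    else:
        raise ValueError(f"unknown desolvation solver {solver!r}")
    return EnergyDecomposition(dG_ES=dg_es, dG_DS=dg_ds, solver=solver)


def regression_with_normality_gate(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> RegressionResult:
    """OLS when both series pass Shapiro-Wilk at ``alpha``; else Spearman.

    The OLS p-value is the two-tailed F/t test of zero slope (identical for a
    single predictor). In the Spearman branch ``r_squared`` is ρ² and the
    slope/intercept still report the least-squares line for plotting.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")

    def _shapiro_p(v: np.ndarray) -> float:
        if np.ptp(v) == 0:
            return 0.0  # degenerate: certainly not normal
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(stats.shapiro(v).pvalue)

    norm_p = min(_shapiro_p(x), _shapiro_p(y))
    fit = stats.linregress(x, y)
    if norm_p > alpha:
        return RegressionResult(
            slope=float(fit.slope),
            intercept=float(fit.intercept),
            r_squared=float(fit.rvalue**2),
            p_value=float(fit.pvalue),
            method="pearson_ols",
            normality_p=norm_p,
        )
    rho, p = stats.spearmanr(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(rho**2),
        p_value=float(p),
        method="spearman",
        normality_p=norm_p,
    )


@dataclass
class MutantTableReport:
    """Recomputed ΔΔG_OBS plus the three cross-column regressions."""

    table: pd.DataFrame  # printed columns + ddG_OBS_recomputed + residual
    es_vs_obs: RegressionResult
    ds_vs_obs: RegressionResult
    es_vs_ds: RegressionResult
    temperature: float

    def report_text(self) -> str:
        def fmt(name: str, r: RegressionResult) -> str:
            # r^2 floored to two decimals: never overstate a fit (0.9997 -> 0.99)
            r2 = math.floor(r.r_squared * 100) / 100
            return (
                f"{name}: r^2 = {r2:.2f}  p = {r.p_value:.3g}  "
                f"slope = {r.slope:.3f}  method = {r.method}"
            )

        lines = [
            f"temperature: {self.temperature:g} K "
            f"(RT = {GAS_CONSTANT_KCAL * self.temperature:.3f} kcal/mol)",
            fmt("ddG_ES vs ddG_OBS", self.es_vs_obs),
            fmt("ddG_DS vs ddG_OBS", self.ds_vs_obs),
            fmt("ddG_ES vs ddG_DS ", self.es_vs_ds),
        ]
        return "\n".join(lines)


def mutant_table_analysis(
    records: Iterable[MutantRecord], temperature: float = 298.0
) -> MutantTableReport:
    """Recompute ΔΔG_OBS from Kd and regress the published ΔΔ columns.

    ΔΔG_OBS is always taken against the wild-type row's Kd (that is how the
    published values were derived); the per-record ``comparator`` annotates
    which variant the ΔΔG_ES/ΔΔG_DS columns are differenced against. The three
    regressions use the columns as printed.
    """
    records = list(records)
    by_label = {r.label: r for r in records}
    if "Wt" not in by_label:
        raise ValueError("table has no 'Wt' reference row")
    if len(records) < 3:
        raise ValueError("degenerate table: need >= 3 rows for the regressions")
    kd_wt = by_label["Wt"].Kd_nM

    rows = []
    for r in records:
        if r.comparator not in by_label:
            raise ValueError(f"{r.label}: comparator {r.comparator!r} not in table")
        recomputed = ddg_from_kd(r.Kd_nM, kd_wt, temperature)
        rows.append(
            {
                "label": r.label,
                "ddG_ES": r.ddG_ES,
                "ddG_DS": r.ddG_DS,
                "Kd_nM": r.Kd_nM,
                "ddG_OBS": r.ddG_OBS,
                "ddG_OBS_recomputed": recomputed,
                "residual": recomputed - r.ddG_OBS,
                "comparator": r.comparator,
            }
        )
    df = pd.DataFrame(rows)
    es, ds, obs = df["ddG_ES"], df["ddG_DS"], df["ddG_OBS"]
    return MutantTableReport(
        table=df,
        es_vs_obs=regression_with_normality_gate(es, obs),
        ds_vs_obs=regression_with_normality_gate(ds, obs),
        es_vs_ds=regression_with_normality_gate(es, ds),
        temperature=temperature,
    )
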