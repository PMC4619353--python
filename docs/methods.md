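# Methods

## Model

The package treats a protein as a rigid set of heavy atoms with fixed partial
charges and computes, at selected surface loci, the multi-body screened
Coulomb potential

G_ES(i) = s · Σ_j k·q_j / (ε(r_ij)·r_ij), k = 332.0636 kcal·Å/(mol·e²),

summing over every atom j outside the locus's own residue. This is a
continuum-free, pairwise electrostatic model: no reaction field, no ionic
screening, no polarization. Its purpose is ranking loci on one structure, not
absolute energies; all of the package's statistics are location- and
scale-invariant, so conclusions depend only on relative potentials.

Assumptions worth stating explicitly:

- **Rigid, heavy-atom structures.** Crystal structures carry no hydrogens and
  none are built; charge templates fold hydrogen charges into the parent
  heavy atom. No rotamer building, pKa prediction or minimization.
- **Probe sign.** s = −1 by default: the potential is reported as felt by a
  unit *anionic* probe, so electropositive environments give negative
  ("high") G_ES and the most GAG-attractive locus is the minimum of the
  table. s = +1 exposes the raw electropositive potential.
- **Exclusion set.** The locus's whole residue is excluded (not just the
  locus atom), avoiding self-polarization by the residue's own dipole; a
  "self" mode (exclude only the atom) exists for sensitivity checks.
- **No cutoff radius.** Structures of interest are small; the full N-body
  sum is exact and cheap.
- **His is neutral by default** (its protonation state near physiological pH
  is genuinely ambiguous); a flag provides a +1 His formal model, and His
  ring nitrogens drop out of the neutral-donor catalog whenever the residue's
  model charge is non-neutral.

## Loci

Two donor classes are cataloged. Basic donors: Arg NE/NH1/NH2, Lys NZ.
Neutral donors: the strict catalog is Asn ND2 and Gln NE2; the extended
(default) catalog adds Ser OG, Thr OG1, Tyr OH, Trp NE1 and His ND1/NE2.
Which neutral donors beyond Asn/Gln belong in the catalog is an open modeling
choice; both catalogs are exposed so the minimal Asn/Gln-only reading is one
flag away. Potentials are evaluated and reported per donor atom; an optional
per-residue aggregation keeps the most negative atom of each residue.

## Charge models

Three residue-template models ship as TSV data:

- `formal` — ±1 formal charges spread over the terminal group (Lys NZ +1,
  Arg NH1/NH2 +0.5 each, Asp/Glu carboxylate oxygens −0.5 each, all else 0).
  Default, and the most transparent for toy structures.
- `charmm-like` — heavy-atom charges derived from the CHARMM22/36 protein
  topologies with hydrogen charges folded into their parent atom.
- `mmff94-like` — a coarser bond-increment-style spread with a stronger
  backbone dipole.

Each template sums to the residue's formal charge within 0.01 e (validated at
load). These are artifact-level template sets — deliberately simple, not
verbatim force-field exports; the pipeline's statistics depend on relative
potentials and are robust to the choice, which the dielectric/charge-model
sweep tests exercise.

## Dielectric treatment

Uniform ε (default 4, selectable 2/3/10 or any positive value) or a
distance-dependent ε(r) = ε·r. Under a uniform dielectric every potential
scales as 1/ε, so donor rankings — and therefore hot-spot identity — are
mathematically invariant across the sweep; the sweep test documents this
rather than discovering it, and guards the distance-dependent path.

## 2DSE projection

A locus at (x, y, z) maps to (ρ, z), ρ = (x²+y²)^½. Marker area is
min(exp((G_ref − G)/RT), cap) with RT = 0.593 kcal/mol (298 K) and cap = e⁵.
The reference G_ref defaults to the mean over plotted loci (area 1 = average
locus); "least negative" and explicit values are selectable. The cap is
purely presentational — uncapped area ratios satisfy
area_i/area_j = exp((G_j − G_i)/RT) to machine precision, which is the tested
contract. Projection uses deposited coordinates by default ("raw"); a
"centroid" origin rule is offered because deposited frames are arbitrary, and
the plot is exactly invariant under rotation about z and shifts along z.

## Hot-spot statistic

Over the neutral-donor potentials of one structure: mean, sample sd (ddof 1),
minimum, skewness and Shapiro–Wilk normality p. A hot spot is a locus with
z = (G − mean)/sd ≤ −2.0 (configurable); a structure is *specific* iff it has
at least one. The published criterion is verbal ("significantly higher than
the average, long tails"), so the numeric threshold is this package's own
declared choice; normality p and skewness are reported as supporting evidence
and never gate the verdict. Note the sample-z bound |z| ≤ (n−1)/√n: with few
donors (n ≲ 6) no locus can reach |z| = 2, so verdicts on very small tables
are structurally conservative, and fewer than 3 donors is an error. Each hot
spot is annotated with the Arg/Lys residues whose terminal sidechain
nitrogens lie within 12 Å (minimum distance per residue) — the constellation
report.

## Energetics

ΔΔG_OBS = RT ln(Kd_mut/Kd_ref) with R = 1.9872×10⁻³ kcal/(mol·K), T = 298 K
by default. In the packaged tables the Kd reference is always the wild type —
that is how the published ΔΔG_OBS values reproduce to one decimal — while the
per-record `comparator` field annotates which variant the ΔΔG_ES/ΔΔG_DS
columns are differenced against (the double mutants are differenced against
their single-mutant parent). The thrombin table's printed ΔΔG_OBS values are
most consistent with RT ≈ 0.60 kcal/mol (T ≈ 303 K); temperature is a
parameter and the printed columns are treated as data either way. One
antithrombin double mutant's ΔΔG_OBS (7.6) derives from an external source
and is not exactly recovered from its printed Kd at 298 K; it is reported
with its residual like every other row.

The decomposition contract: ΔG_ES is the inter-partner Coulomb cross-sum at
inner dielectric 2 (intra-partner terms cancel in complex-minus-parts for
rigid partners); ΔG_DS comes from a pluggable solver. The shipped
`born_surrogate` gives each charged atom an effective Born radius growing
linearly with burial (R = 2.0 Å + 0.1 Å per non-self heavy atom within 6 Å,
partner atoms included in the complex state) and charges
−(k/2)·q²·(1/ε_out − 1/ε_in)·(1/R_alone − 1/R_complex) per atom with
ε_in = 2, ε_out = 80. It is a deliberately minimal generalized-Born-style
model of this package's own design: it guarantees zero in the separated
limit, a non-negative penalty when binding only adds burial, q² scaling, and
the sign-opposition of ΔΔG_ES vs ΔΔG_DS under charge perturbations — the
qualitative laws the analysis needs — and makes no claim to grid
Poisson–Boltzmann accuracy.

Regressions pass through a normality gate: ordinary least squares with the
two-tailed F/t test when both series pass Shapiro–Wilk at α = 0.05, Spearman
rank correlation (r² = ρ²) otherwise. Both packaged tables pass the gate, so
the published statistics are reproduced on the OLS branch. Text reports floor
r² to two decimals (0.9997 prints as 0.99) so a fit is never overstated;
machine-readable outputs carry full precision.

## Synthetic structures

The generator emits legal PDB structures from minimal real residues (each
donor residue is a CA plus its donor atom; Lys is CA + NZ; Asp is
CA + OD1/OD2), so the full reading/charging/scanning pipeline is exercised.

- *Specific*: one Asn ND2 at the origin ringed by `n_basic` = 4 Lys NZ at
  `ring_radius` = 8 Å (0.5 Å positional noise), 24 background donors on a
  25–45 Å shell, and six Lys/Asp pairs placed ~3.5 Å apart as net-neutral
  dipoles so the far field decays as 1/r². At generation time the structure
  is verified with the brute-force oracle: the planted donor must be the
  minimum and sit ≥ 4 sd below the donor mean, else the seed is re-drawn
  (deterministically) and the build repeated.
- *Nonspecific*: the same atom budget with every position scattered
  (donors kept ≥ 8 Å from any charge). Because donors are neutral, each
  donor's potential depends only on the fixed charge field, so offending
  donors are individually resampled until no donor deviates more than 1.5 sd
  from the mean; the finished structure is then re-verified with the oracle.

Defaults (4 ring charges, 25 donors, 8 Å ring, 0.5 Å noise) were chosen so
the planted signal clears the z ≤ −2 detection rule with a ≥ 4 sd margin —
note 25 donors are needed for a 4 sd excursion to be possible at all, given
the sample-z bound above. What these fixtures emulate is the *geometry* of a
specific site (a donor inside a basic constellation) and the *statistics* of
a diffuse one; what they do not emulate is real protein packing, backbone
dipole density, or solvent screening. Passing the recovery tests therefore
demonstrates that the statistic detects the planted geometry reliably, not
that real structures are classified with the same accuracy.

## Numerical choices

- Coulomb constant 332.0636 kcal·Å/(mol·e²); gas constant
  1.9872×10⁻³ kcal/(mol·K).
- Coincident atoms (r < 10⁻⁶ Å) raise rather than produce infinities.
- Alt-loc tie-break: first-listed conformer, deterministic.
- Sorting of loci by (chain, residue number, insertion code, atom name)
  makes outputs independent of file atom order.
- PDB coordinates are rounded to their native 3 decimals on read, making
  write/read round-trips exact.
- Shapiro–Wilk on zero-variance data is reported as "not applicable" (NaN)
  rather than an arbitrary p.

## Problem sizes

The test suite and the acceptance script use toy structures of ~90 atoms and
25 donor loci, 100-structure batches for recovery and oracle-agreement
checks, and the two packaged mutant tables (9 and 7 rows). These sizes make
every check exact or high-margin while keeping the whole suite in the
seconds-to-minutes range on a single CPU.

## Known limitations

- No grid Poisson–Boltzmann, salt screening or polarizability; absolute
  ΔG_ES/ΔG_DS values from such solvers are treated as data, not reproduced.
- The z ≤ −2 hot-spot rule is a declared convention; structures whose true
  sites produce milder excursions will be called nonspecific.
- Donor catalogs are residue-name-based; modified residues or non-standard
  names fall outside them (and unknown residues get the model's default
  charge, with a warning).
- In-silico mutation is charge-level only (`to_ala`, `silence_charge`,
  `charge_swap`); no sidechain geometry is built, so `charge_swap` places +1
  on the outermost retained sidechain atom rather than modeling a rotamer.
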