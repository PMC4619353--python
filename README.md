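# gagsite

Locate glycosaminoglycan (GAG)-binding sites on protein structures and
classify their specificity from electrostatic potentials at **neutral
hydrogen-bond donors**.

Sulfated GAGs such as heparin bind hundreds of proteins, mostly through
long-range Coulomb attraction to surface Arg/Lys clusters — which is why most
GAG–protein pairs are written off as nonspecific. Yet some systems
(antithrombin–heparin being the classic case) are exquisitely specific. The
idea implemented here: specificity is *not* encoded in the basic residues
themselves but in a strategically placed **uncharged** donor (Asn ND2,
Gln NE2, ...) sitting inside a constellation of Arg/Lys. That donor feels an
unusually high (strongly negative, by the anionic-probe convention)
electrostatic potential, hydrogen-bonds to GAG sulfates with a smaller
desolvation penalty than an ion pair would incur, and thereby pins a unique
binding geometry.

## The method

For a cleaned, heavy-atom structure with template partial charges, the
multi-body potential manifested at a donor locus *i* is the screened Coulomb
sum over all atoms *j* outside the locus's own residue:

```
G_ES(i) = s · Σ_j k q_j / (ε(r_ij) · r_ij)      k = 332.0636 kcal·Å/(mol·e²)
```

with probe sign *s* = −1 (an electropositive environment gives negative
G_ES — attractive to an anionic ligand) and a uniform dielectric ε = 4 by
default (2, 3 and 10, and a distance-dependent ε(r) = ε·r, are available).
Restricted to neutral donors this quantity is called **G_GAG-binding**.

The two-step algorithm:

1. **Map.** Evaluate G_GAG-binding at every neutral donor and project each
   locus from (x, y, z) onto a 2D-Surface-Energy (2DSE) scatter at
   (ρ, z) = ((x²+y²)^½, z), marker area scaled by
   exp((G_ref − G)/RT) so area ratios equal implied affinity ratios
   (K₂/K₁ = e^{ΔΔG/RT}).
2. **Test.** Summarize the donor-potential distribution (mean, sd, skewness,
   Shapiro–Wilk normality) and flag hot spots: loci with
   z = (G − mean)/sd ≤ −2. At least one hot spot ⇒ a *specific* site; a
   diffuse, tail-free distribution ⇒ *nonspecific*. Each hot spot is
   annotated with the Arg/Lys residues whose terminal sidechain nitrogens lie
   within 12 Å — the constellation responsible for the bias.

A companion energetics module converts dissociation constants to observed
binding free-energy differences, ΔΔG_OBS = RT ln(Kd_mut/Kd_wt), decomposes
complex energetics into electrostatic and desolvation components
(complex-minus-parts, with a pluggable generalized-Born-style surrogate
solver), and reproduces the published antithrombin/thrombin mutant analysis:
electrostatic gains are almost exactly opposed by desolvation penalties
(r² ≈ 0.99), while either component alone tracks ΔΔG_OBS only moderately
(r² ≈ 0.6–0.7).

## Worked example

```sh
python examples/scan_synthetic_site.py
```

builds a toy structure with a planted specific site (an Asn donor ringed by
four Lys at 8 Å) and prints:

```
--- planted specific structure ---
structure: synthetic-specific-11
verdict: specific
loci: n=25  mean=-11.677  sd=6.998  min=-43.019 kcal/mol
skewness: -3.780
Shapiro-Wilk normality p: 0.0000
hot-spot criterion: z <= -2
hot spots: 1
  A:ASN 1:ND2  G_ES=-43.019  z=-4.48
    near A:LYS 5 at 7.3 Å
    ...
```

The planted donor is the one hot spot, 4.5 sd below the donor mean, and the
report lists its four-Lys constellation with distances. The matching
nonspecific structure (same atom budget, scattered charges) returns
`verdict: nonspecific` with zero hot spots and near-zero skewness.
`examples/mutant_energetics.py` prints the mutant-table regressions
(`ddG_ES vs ddG_DS : r^2 = 0.99` for both systems) together with the
recomputed ΔΔG_OBS column, e.g. K125Q: Kd 12 vs 6 nM → 0.41 kcal/mol against
the printed 0.4.

The same pipeline runs on any PDB file from the shell:

```sh
gagsite scan --pdb protein.pdb --charge-model charmm-like --out results/
gagsite mutants --system thrombin --out results/
gagsite simulate --kind specific --seed 7 --out fixtures/
```

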