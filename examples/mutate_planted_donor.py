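"""Hot-spot destruction by in-silico mutation of the planted donor.

Scans a planted-specific structure, then replaces the planted Asn with Ala
and rescans. The hot spot exists only while the neutral donor sits inside its
basic-residue constellation: removing the donor removes the hot spot.
"""

from gagsite import (
    SiteSpec,
    all_locus_potentials,
    assign_charges,
    classify_specificity,
    load_charge_model,
    make_structure,
    mutate_residue,
)

s = assign_charges(make_structure(SiteSpec(kind="specific", seed=3)), load_charge_model("formal"))
before = classify_specificity(all_locus_potentials(s, "neutral_donor"), s)
print("wild type:", before.verdict, "| hot spots:", [h.locus.label for h in before.hotspots])

mutated = mutate_residue(s, chain="A", residue_number=1, mode="to_ala")
after = classify_specificity(all_locus_potentials(mutated, "neutral_donor"), mutated)
print("N1A mutant:", after.verdict, "| hot spots:", [h.locus.label for h in after.hotspots])
print("(the planted donor locus no longer exists, so its hot spot is gone)")
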