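"""Prioritize a recessive candidate variant in a family quartet.

Two affected full siblings, their obligate-carrier parents, and two
control panels. One protein-changing variant is planted so that it — and
only it — satisfies every filter: high predicted effect, recessive
segregation, absent from the first panel, and at most one heterozygous
carrier in the second.
"""

from pedscout import (
    CohortDesign,
    EffectTier,
    PanelPolicy,
    gen_quartet_cohort,
    panel_lookup,
    run_funnel,
)

cohort = gen_quartet_cohort(CohortDesign(seed=7))
panels = [panel_lookup(pv) for pv in cohort.panel_variants]

candidates, report = run_funnel(
    cohort.family_variants,
    cohort.roles,
    EffectTier(),
    panels,
    [PanelPolicy(max_het_carriers=0, max_hom_alt=0),
     PanelPolicy(max_het_carriers=1, max_hom_alt=0)],
)

print("funnel:")
for label, count in report.stages:
    print(f"  {label:<12} {count:>6}")
print("\ncandidates:")
for v in candidates:
    print(f"  chr{v.chrom}:{v.pos} {v.ref}>{v.alt} ({v.consequence})")
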