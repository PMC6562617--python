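"""Estimate per-breed allele frequencies for the candidate variant.

The bundled genotype-count triples (hom-ref, het, hom-alt per breed) are
expanded into a per-sample table, re-tabulated — including a second Giant
Schnauzer row with close relatives of the affected family removed — and
turned into the reported frequency table. Frequencies use
(het + 2*hom_alt) / (2N) and are rounded half-up to three decimals; a `*`
marks the relative-excluded cohort.
"""

from pedscout import frequency_table, homozygote_census, tabulate_cohorts
from pedscout.datasets import BREED_GENOTYPE_COUNTS
from pedscout.simulate import gen_cohort_table

table, related = gen_cohort_table(
    BREED_GENOTYPE_COUNTS, related_removed={"Giant Schnauzer": (1, 9, 3)}
)
print(f"{len(table)} genotyped dogs across {table['breed'].nunique()} cohorts")

cohorts = tabulate_cohorts(table, related)
print(frequency_table(cohorts).to_string(index=False))

census = homozygote_census(table)
print(f"\nhomozygous-alternate dogs: {len(census)} "
      f"(breeds: {', '.join(sorted(set(census['breed'])))})")
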