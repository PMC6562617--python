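"""Measure the shared disease-haplotype extent across carrier breeds.

Markers flanking the candidate variant are tagged with the disease allele
(the allele every affected dog is homozygous for), then each carrier is
walked outward from the candidate until its genotype can no longer carry
that allele. Breeds that split from the founder longer ago have had more
recombination, so their shared extent is shorter — the expected ordering
is Giant Schnauzer > Giant Spitz > Dachshund.
"""

from pedscout import carrier_extent, disease_alleles
from pedscout.haplotype import extents_table
from pedscout.simulate import gen_flanking_panel

panel, truth = gen_flanking_panel(seed=7)
print(f"panel: {len(panel.positions)} markers around "
      f"chr27:{panel.candidate_position:,}")

alleles = disease_alleles(panel, ["GS_CASE1", "GS_CASE2"])
print("disease alleles per marker:", alleles)

extents = [
    carrier_extent(panel, alleles, sample)
    for sample in ("GS_CARRIER", "SPITZ_CARRIER", "DACH_CARRIER")
]
print()
print(extents_table(extents).to_string(index=False))
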