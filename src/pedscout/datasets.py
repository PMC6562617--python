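"""Bundled reference tables from the Giant Schnauzer PRA / NECAP1 case study.

These are the published summary data of the motivating study — breed
genotype counts for the NECAP1 c.544G>A variant, the case-shared runs of
homozygosity, and the retinal RNA-seq exon summaries — kept here so the
pipeline's reporting operations can be exercised and reproduced without any
external download. Coordinates are CanFam3.1, 1-based.
"""

from __future__ import annotations

from .cohorts import CohortCounts
from .core import GeneInterval

#: The candidate causal variant: NECAP1 c.544G>A (p.Gly182Arg), exon 6 of 8.
CANDIDATE_VARIANT = {
    "chrom": "27",
    "pos": 37_468_611,
    "ref": "G",
    "alt": "A",
    "consequence": "missense_variant",
    "gene": "NECAP1",
}

#: NECAP1 gene span on chromosome 27 (CanFam3.1).
NECAP1_GENE = GeneInterval(chrom="27", start=37_460_607, end=37_506_942, name="NECAP1")

#: Per-breed genotype counts (hom-ref, het, hom-alt) for c.544G>A.
#: "GS *" is the Giant Schnauzer cohort with known close relatives
#: (up to three generations) of the probands removed.
BREED_GENOTYPE_COUNTS: tuple[CohortCounts, ...] = (
    CohortCounts("Giant Schnauzer", 301, 18, 3),
    CohortCounts("Giant Schnauzer", 300, 9, 0, exclude_related=True),
    CohortCounts("Giant Spitz", 106, 7, 0),
    CohortCounts("Medium Spitz", 146, 5, 0),
    CohortCounts("Miniature Spitz", 106, 8, 0),
    CohortCounts("Pomeranian Spitz", 56, 3, 0),
    CohortCounts("Miniature Longhaired Dachshund", 157, 8, 0),
    CohortCounts("Other breeds or unknown", 4206, 0, 0),
)

#: Printed allele frequencies accompanying the count rows above
#: (no frequency is reported for the pooled other-breeds row).
PUBLISHED_FREQUENCIES: dict[str, float] = {
    "Giant Schnauzer": 0.037,
    "Giant Schnauzer *": 0.015,
    "Giant Spitz": 0.031,
    "Medium Spitz": 0.017,
    "Miniature Spitz": 0.035,
    "Pomeranian Spitz": 0.025,
    "Miniature Longhaired Dachshund": 0.024,
}

#: The 13 runs of homozygosity > 1 Mb shared by both sequenced PRA cases:
#: (chromosome, start bp, end bp) with the published size in Mb.
CASE_SHARED_ROH: tuple[tuple[str, int, int, float], ...] = (
    ("1", 29_970_719, 33_682_751, 3.71),
    ("6", 33_954_067, 39_111_638, 5.16),
    ("8", 59_486_837, 65_640_116, 6.15),
    ("10", 64_657_382, 69_250_914, 4.59),
    ("13", 58_887_427, 60_841_228, 1.95),
    ("21", 12_842_407, 19_235_893, 6.39),
    ("23", 54_039, 17_493_091, 17.44),
    ("25", 23_239_981, 26_009_032, 2.77),
    ("27", 36_722_004, 45_753_342, 9.03),
    ("28", 13_922_125, 15_662_789, 1.74),
    ("29", 38_572_915, 41_054_487, 2.48),
    ("30", 1_366, 26_126_946, 26.13),
    ("36", 17_518_975, 21_096_460, 3.58),
)

#: Retinal RNA-seq exon summaries: gene -> (chrom, start, end, total exonic
#: reads, published mean reads per exon). RPGRIP1/RHO/GNAT1 are retina-
#: expressed controls; ANXA1/MYH41/MYOT have low/no retinal expression.
RETINA_EXON_SUMMARY: dict[str, tuple[str, int, int, int, int]] = {
    "RPGRIP1": ("15", 18_316_887, 18_387_548, 1_458, 58),
    "RHO": ("20", 5_632_150, 5_637_404, 461_640, 92_328),
    "GNAT1": ("20", 39_129_469, 39_133_156, 118_800, 13_200),
    "ANXA1": ("1", 84_744_444, 84_763_121, 120, 9),
    "MYH41": ("5", 34_748_657, 34_767_076, 3, 0),
    "MYOT": ("11", 25_591_798, 25_592_328, 40, 4),
    "NECAP1": ("27", 37_460_607, 37_506_942, 749, 94),
}

#: NECAP1 exon structure facts used by the synthetic exon-count generator:
#: 8 exons; 288 of the 749 retinal reads aligned over exon 6.
NECAP1_N_EXONS = 8
NECAP1_EXON6_READS = 288

RETINA_EXPRESSED_CONTROLS = ("RPGRIP1", "RHO", "GNAT1")
RETINA_NON_EXPRESSED_CONTROLS = ("ANXA1", "MYH41", "MYOT")
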