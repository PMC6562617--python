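"""Seeded synthetic-data generators for every input the pipeline consumes.

Each generator is deterministic for a given design + seed and returns a
truth record sufficient to score the downstream module without re-deriving
ground truth:

* :func:`gen_quartet_cohort` — a sequenced family (affected siblings,
  obligate-carrier parents, optional unaffected siblings) plus control
  panels, with one planted causal variant that satisfies every funnel
  criterion and background variants each constructed to violate exactly
  one criterion (adversarial by category, so funnel stage counts are
  predictable);
* :func:`gen_marker_grid` — SNP-array-like marker grids with planted
  autozygous blocks inside heterozygous flanks;
* :func:`gen_cohort_table` — per-sample genotype rows expanding per-breed
  count triples (the counting operation inverts it exactly);
* :func:`gen_exon_counts` — Poisson per-exon read counts at stated rates;
* :func:`gen_flanking_panel` — a flanking-marker panel with nested shared
  haplotypes across three breeds.

Default design sizes mirror the motivating study: two affected full
siblings and both parents sequenced, control panels of 112 and 452
genomes, and one heterozygous carrier of the planted variant in the
second panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohorts import CohortCounts
from .core import (
    GenotypeCall,
    Interval,
    MarkerGrid,
    Role,
    SampleRole,
    Variant,
    write_bed,
    write_vcf,
)
from .datasets import CANDIDATE_VARIANT
from .haplotype import FlankingPanel

_BASES = ("A", "C", "G", "T")

LOW_EFFECT_TERMS = ("synonymous_variant", "intron_variant", "intergenic_variant",
                    "upstream_gene_variant", "3_prime_UTR_variant")
HIGH_EFFECT_TERMS = ("missense_variant", "stop_gained", "splice_donor_variant",
                     "frameshift_variant", "inframe_deletion")

#: Background-variant categories; each violates exactly the named criterion.
BACKGROUND_CATEGORIES = (
    "low_effect",          # fails the effect-tier filter
    "case_not_hom_alt",    # fails segregation: an affected sample is not hom-alt
    "parent_not_het",      # fails segregation: an obligate carrier is not het
    "unaffected_hom_alt",  # fails segregation: an unaffected sib is hom-alt
    "panel1_carrier",      # fails the first (zero-tolerance) control panel
    "panel2_hom_alt",      # fails the second panel (a hom-alt control)
)


# ---------------------------------------------------------------------------
# Quartet cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortDesign:
    """Design of a synthetic sequenced family + control panels."""

    n_cases: int = 2
    n_unaffected_sibs: int = 0
    panel_sizes: tuple[int, ...] = (112, 452)
    n_background_variants: int = 999
    planted_chrom: str = CANDIDATE_VARIANT["chrom"]
    planted_pos: int = CANDIDATE_VARIANT["pos"]
    planted_ref: str = CANDIDATE_VARIANT["ref"]
    planted_alt: str = CANDIDATE_VARIANT["alt"]
    planted_consequence: str = CANDIDATE_VARIANT["consequence"]
    #: het carriers of the planted variant in the last panel (the study found
    #: one, in a Giant Spitz, tolerated by a max-1-het policy there)
    planted_last_panel_hets: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("need at least one affected sample")
        if self.planted_consequence not in HIGH_EFFECT_TERMS:
            raise ValueError(
                "planted causal variant must carry a protein-changing consequence"
            )
        if not self.panel_sizes:
            raise ValueError("need at least one control panel")
        if self.planted_last_panel_hets > self.panel_sizes[-1]:
            raise ValueError("more planted panel carriers than panel samples")


@dataclass
class QuartetCohort:
    """In-memory synthetic cohort plus its truth record."""

    family_variants: list[Variant]
    panel_variants: list[list[Variant]]
    roles: list[SampleRole]
    truth: dict

    @property
    def family_samples(self) -> list[str]:
        return [r.sample_id for r in self.roles if r.role is not Role.PANEL_CONTROL]


def _family_samples(design: CohortDesign) -> tuple[list[str], list[str], list[str]]:
    cases = [f"CASE{i + 1}" for i in range(design.n_cases)]
    parents = ["SIRE", "DAM"]
    sibs = [f"SIB{i + 1}" for i in range(design.n_unaffected_sibs)]
    return cases, parents, sibs


def gen_quartet_cohort(design: CohortDesign) -> QuartetCohort:
    """Generate the family VCF contents, panel genotypes, roles and truth."""
    rng = np.random.default_rng(design.seed)
    cases, parents, sibs = _family_samples(design)
    panels = [
        [f"P{p + 1}_{i + 1:04d}" for i in range(n)]
        for p, n in enumerate(design.panel_sizes)
    ]

    categories = [c for c in BACKGROUND_CATEGORIES
                  if c != "unaffected_hom_alt" or sibs]

    # unique positions for background variants
    used = {(design.planted_chrom, design.planted_pos)}
    sites: list[tuple[str, int]] = []
    while len(sites) < design.n_background_variants:
        chrom = str(rng.integers(1, 39))
        pos = int(rng.integers(1, 120_000_000))
        if (chrom, pos) not in used:
            used.add((chrom, pos))
            sites.append((chrom, pos))

    family_variants: list[Variant] = []
    panel_variants: list[list[Variant]] = [[] for _ in panels]
    category_of: dict[str, str] = {}

    def build(chrom, pos, ref, alt, consequence, fam_gt, panel_gt):
        family_variants.append(
            Variant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                    consequence=consequence, genotypes=fam_gt)
        )
        for p, gts in enumerate(panel_gt):
            panel_variants[p].append(
                Variant(chrom=chrom, pos=pos, ref=ref, alt=alt,
                        consequence=consequence, genotypes=gts)
            )

    def segregating_family() -> dict[str, GenotypeCall]:
        gt = {c: GenotypeCall.HOM_ALT for c in cases}
        gt |= {p: GenotypeCall.HET for p in parents}
        for s in sibs:
            gt[s] = GenotypeCall.HET if rng.random() < 0.5 else GenotypeCall.HOM_REF
        return gt

    def clear_panels() -> list[dict[str, GenotypeCall]]:
        return [{s: GenotypeCall.HOM_REF for s in panel} for panel in panels]

    # --- planted causal variant ------------------------------------------
    planted_panels = clear_panels()
    for i in range(design.planted_last_panel_hets):
        planted_panels[-1][panels[-1][i]] = GenotypeCall.HET
    build(
        design.planted_chrom, design.planted_pos, design.planted_ref,
        design.planted_alt, design.planted_consequence,
        segregating_family(), planted_panels,
    )
    planted_key = (design.planted_chrom, design.planted_pos,
                   design.planted_ref, design.planted_alt)

    # --- adversarial background ------------------------------------------
    n_per_category = {c: 0 for c in categories}
    for i, (chrom, pos) in enumerate(sites):
        category = categories[i % len(categories)]
        n_per_category[category] += 1
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        consequence = (
            str(rng.choice(LOW_EFFECT_TERMS))
            if category == "low_effect"
            else str(rng.choice(HIGH_EFFECT_TERMS))
        )
        fam = segregating_family()
        pnl = clear_panels()
        if category == "case_not_hom_alt":
            fam[str(rng.choice(cases))] = (
                GenotypeCall.HET if rng.random() < 0.5 else GenotypeCall.HOM_REF
            )
        elif category == "parent_not_het":
            fam[str(rng.choice(parents))] = (
                GenotypeCall.HOM_REF if rng.random() < 0.5 else GenotypeCall.HOM_ALT
            )
        elif category == "unaffected_hom_alt":
            fam[str(rng.choice(sibs))] = GenotypeCall.HOM_ALT
        elif category == "panel1_carrier":
            carrier = str(rng.choice(panels[0]))
            pnl[0][carrier] = (
                GenotypeCall.HET if rng.random() < 0.5 else GenotypeCall.HOM_ALT
            )
        elif category == "panel2_hom_alt":
            pnl[-1][str(rng.choice(panels[-1]))] = GenotypeCall.HOM_ALT
        build(str(chrom), int(pos), str(ref), str(alt), consequence, fam, pnl)
        category_of[f"{chrom}:{pos}"] = category

    # --- roles -------------------------------------------------------------
    roles = [SampleRole(c, Role.CASE, "Giant_Schnauzer") for c in cases]
    roles += [SampleRole(p, Role.OBLIGATE_CARRIER, "Giant_Schnauzer") for p in parents]
    roles += [SampleRole(s, Role.UNAFFECTED, "Giant_Schnauzer") for s in sibs]
    breeds = ("Labrador", "Vizsla", "Beagle", "Border_Collie", "Whippet")
    for p, panel in enumerate(panels):
        for i, s in enumerate(panel):
            if p == len(panels) - 1 and i < design.planted_last_panel_hets:
                breed = "Giant_Spitz"
            else:
                breed = str(rng.choice(breeds))
            roles.append(SampleRole(s, Role.PANEL_CONTROL, breed))

    # expected funnel counts given sequential stages:
    # all -> high effect -> segregating -> panel 1 ... panel k
    n_total = 1 + design.n_background_variants
    expected = [n_total, n_total - n_per_category["low_effect"]]
    n_seg = 1 + n_per_category["panel1_carrier"] + n_per_category["panel2_hom_alt"]
    expected.append(n_seg)
    expected.append(n_seg - n_per_category["panel1_carrier"])
    if len(panels) > 1:
        expected.append(1)

    truth = {
        "planted_key": list(planted_key),
        "category_counts": n_per_category,
        "category_of": category_of,
        "expected_funnel_counts": expected,
        "seed": design.seed,
    }
    return QuartetCohort(family_variants, panel_variants, roles, truth)


def gen_quartet_vcf(design: CohortDesign, outdir: str | Path) -> dict[str, Path]:
    """Write the synthetic cohort to disk: family VCF, panel VCFs, pedigree, truth.

    Deterministic for a given design: two runs with the same seed produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = gen_quartet_cohort(design)

    paths = {"family_vcf": outdir / "family.vcf",
             "pedigree": outdir / "pedigree.tsv",
             "truth": outdir / "truth.json"}
    contigs = [str(c) for c in range(1, 39)]
    write_vcf(cohort.family_variants, cohort.family_samples,
              paths["family_vcf"], contigs=contigs)
    for p, variants in enumerate(cohort.panel_variants):
        path = outdir / f"panel{p + 1}.vcf"
        samples = [r.sample_id for r in cohort.roles
                   if r.role is Role.PANEL_CONTROL and r.sample_id.startswith(f"P{p + 1}_")]
        write_vcf(variants, samples, path, contigs=contigs)
        paths[f"panel{p + 1}_vcf"] = path
    with open(paths["pedigree"], "w") as fh:
        fh.write("# sample_id\trole\tbreed\n")
        for r in cohort.roles:
            fh.write(f"{r.sample_id}\t{r.role.value}\t{r.breed}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Marker grids
# ---------------------------------------------------------------------------


@dataclass
class GridDesign:
    """Design of SNP-array-like marker grids with planted autozygous blocks.

    ``baseline_het`` is the heterozygosity rate outside planted blocks. The
    default 0.25 emulates an outbred genome at array sites; block-recovery
    fixtures typically raise it (see the boundary discussion in the package
    methods documentation) so planted boundaries are sharp at marker scale.
    Inside blocks, calls are homozygous apart from genotyping-error
    heterozygotes at ``block_het`` (default 0.2%).
    """

    chromosomes: dict[str, int] = field(default_factory=lambda: {"27": 45_000_000})
    mean_spacing_bp: int = 20_000
    samples: tuple[str, ...] = ("CASE1", "CASE2", "SIRE", "DAM")
    #: sample -> list of (chrom, start bp, end bp) planted autozygous blocks
    blocks: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    baseline_het: float = 0.25
    block_het: float = 0.002
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_het < 1:
            raise ValueError("baseline_het must be in (0, 1)")
        for sample, blocks in self.blocks.items():
            if sample not in self.samples:
                raise ValueError(f"blocks listed for unknown sample {sample!r}")
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end in blocks:
                if chrom not in self.chromosomes:
                    raise ValueError(f"block on unknown chromosome {chrom!r}")
                if not 1 <= start < end <= self.chromosomes[chrom]:
                    raise ValueError(
                        f"block {chrom}:{start}-{end} outside chromosome span"
                    )
                by_chrom.setdefault(chrom, []).append((start, end))
            for spans in by_chrom.values():
                spans.sort()
                for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                    if s2 <= e1:
                        raise ValueError(f"overlapping planted blocks for {sample!r}")


def gen_marker_grid(design: GridDesign) -> tuple[list[MarkerGrid], dict]:
    """Generate marker grids and the truth record of planted blocks."""
    rng = np.random.default_rng(design.seed)
    grids: list[MarkerGrid] = []
    for chrom, length in design.chromosomes.items():
        spacings = rng.uniform(0.5, 1.5, size=max(4, 2 * length // design.mean_spacing_bp))
        positions = 1 + np.cumsum((spacings * design.mean_spacing_bp).astype(np.int64))
        positions = positions[positions <= length]
        n = positions.size
        genotypes: dict[str, np.ndarray] = {}
        for sample in design.samples:
            in_block = np.zeros(n, dtype=bool)
            for bchrom, start, end in design.blocks.get(sample, []):
                if bchrom == chrom:
                    in_block |= (positions >= start) & (positions <= end)
            u = rng.random(n)
            hom_side = rng.random(n) < 0.5  # hom-ref vs hom-alt when homozygous
            calls = np.where(hom_side, 0, 2).astype(np.int8)
            het_rate = np.where(in_block, design.block_het, design.baseline_het)
            calls[u < het_rate] = 1
            calls[rng.random(n) < design.missing_rate] = -1
            genotypes[sample] = calls
        grids.append(MarkerGrid(chrom=chrom, positions=positions, genotypes=genotypes))
    truth = {"blocks": {s: list(b) for s, b in design.blocks.items()},
             "seed": design.seed,
             "mean_spacing_bp": design.mean_spacing_bp}
    return grids, truth


def write_grid_truth_bed(design: GridDesign, path: str | Path) -> None:
    """Write planted blocks as a BED file (all samples pooled, named by sample)."""
    intervals = []
    for sample, blocks in design.blocks.items():
        for chrom, start, end in blocks:
            intervals.append((sample, Interval(chrom, start, end)))

    class _Named:
        def __init__(self, name, iv):
            self.chrom, self.start, self.end, self.name = iv.chrom, iv.start, iv.end, name

    write_bed([_Named(s, iv) for s, iv in intervals], path, name_field="name")


# ---------------------------------------------------------------------------
# Cohort genotype tables
# ---------------------------------------------------------------------------


def gen_cohort_table(
    cohorts: Sequence[CohortCounts],
    related_removed: dict[str, tuple[int, int, int]] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Expand per-breed genotype count triples into per-sample rows.

    Returns (table, related_sample_ids). ``related_removed`` optionally
    names, per breed, how many (hom-ref, het, hom-alt) samples should be
    marked as close relatives of the probands; re-tabulating with that list
    excluded reproduces a relative-free count row. Rows with
    ``exclude_related=True`` are derived outputs and are skipped here.
    """
    related_removed = related_removed or {}
    rows = []
    related: list[str] = []
    for cohort in cohorts:
        if cohort.exclude_related:
            continue
        slug = cohort.breed.replace(" ", "_")
        n_rel = related_removed.get(cohort.breed, (0, 0, 0))
        for geno_code, count, n_rel_state in zip(
            ("0", "1", "2"),
            (cohort.n_hom_ref, cohort.n_het, cohort.n_hom_alt),
            n_rel,
        ):
            if n_rel_state > count:
                raise ValueError(
                    f"{cohort.breed}: more related samples than genotyped ({geno_code})"
                )
            for i in range(count):
                sample_id = f"{slug}_{geno_code}_{i + 1:04d}"
                rows.append(
                    {"sample_id": sample_id, "breed": cohort.breed, "genotype": geno_code}
                )
                if i < n_rel_state:
                    related.append(sample_id)
    return pd.DataFrame(rows, columns=["sample_id", "breed", "genotype"]), related


# ---------------------------------------------------------------------------
# Exon counts
# ---------------------------------------------------------------------------


def gen_exon_counts(
    gene_specs: dict[str, tuple[str, int, int, list[float]]],
    seed: int = 0,
) -> pd.DataFrame:
    """Poisson per-exon read counts: gene -> (chrom, start, end, per-exon rates)."""
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(gene_specs):
        chrom, start, end, rates = gene_specs[gene]
        if any(r < 0 for r in rates):
            raise ValueError(f"{gene}: exon rates must be non-negative")
        counts = rng.poisson(rates)
        for i, c in enumerate(counts):
            rows.append(
                {"gene": gene, "chrom": chrom, "start": start, "end": end,
                 "exon_index": i + 1, "read_count": int(c)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flanking-marker panels with nested shared haplotypes
# ---------------------------------------------------------------------------


def gen_flanking_panel(
    seed: int = 0,
    n_flank: int = 4,
    candidate_pos: int = CANDIDATE_VARIANT["pos"],
    downstream_kb: float = 573.0,
    upstream_kb: float = 301.0,
) -> tuple[FlankingPanel, dict]:
    """Build a panel with nested shared haplotypes across three breeds.

    Markers sit within ``downstream_kb`` below and ``upstream_kb`` above the
    candidate. Three carrier samples share nested extents of the disease
    haplotype: the case breed shares the whole panel, the Spitz carrier a
    shorter region, and the Dachshund carrier the shortest — emulating
    progressive recombination on an old founder haplotype.

    Truth records the expected (left, right) bound positions per sample.
    """
    rng = np.random.default_rng(seed)
    left = np.sort(rng.integers(1, int(downstream_kb * 1000), size=n_flank))
    right = np.sort(rng.integers(1, int(upstream_kb * 1000), size=n_flank))
    positions = (
        [int(candidate_pos - off) for off in left[::-1]]
        + [candidate_pos]
        + [int(candidate_pos + off) for off in right]
    )
    if len(set(positions)) != len(positions):  # rare collision: nudge
        positions = sorted(set(positions))
        while len(positions) < 2 * n_flank + 1:
            positions.append(positions[-1] + 1000)
        positions.sort()
    n = len(positions)
    ci = positions.index(candidate_pos)
    refs, alts = [], []
    for _ in range(n):
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        refs.append(str(ref))
        alts.append(str(alt))

    # disease allele per marker: alt at the candidate, random elsewhere
    disease = ["alt" if i == ci else str(rng.choice(["ref", "alt"])) for i in range(n)]

    hom = {"ref": GenotypeCall.HOM_REF, "alt": GenotypeCall.HOM_ALT}
    opp = {"ref": GenotypeCall.HOM_ALT, "alt": GenotypeCall.HOM_REF}

    def case_calls() -> list[GenotypeCall]:
        return [hom[d] for d in disease]

    def carrier_calls(reach_left: int, reach_right: int) -> list[GenotypeCall]:
        # het for the disease allele within reach, homozygous-opposite just
        # beyond it, random further out
        calls = []
        for i in range(n):
            if ci - reach_left <= i <= ci + reach_right:
                calls.append(GenotypeCall.HET)
            elif i == ci - reach_left - 1 or i == ci + reach_right + 1:
                calls.append(opp[disease[i]])
            else:
                calls.append(
                    GenotypeCall.HET if rng.random() < 0.5 else opp[disease[i]]
                )
        return calls

    # nested reaches: GS (whole panel) > Giant Spitz > Dachshund
    reach = {"GS_CARRIER": n_flank, "SPITZ_CARRIER": max(1, n_flank // 2),
             "DACH_CARRIER": max(0, n_flank // 2 - 1)}
    genotypes = {"GS_CASE1": case_calls(), "GS_CASE2": case_calls()}
    truth_bounds: dict[str, tuple[int, int]] = {
        "GS_CASE1": (positions[0], positions[-1]),
        "GS_CASE2": (positions[0], positions[-1]),
    }
    for sample, r in reach.items():
        genotypes[sample] = carrier_calls(r, r)
        truth_bounds[sample] = (positions[ci - r], positions[ci + r])

    panel = FlankingPanel(
        positions=positions, refs=refs, alts=alts,
        candidate_index=ci, genotypes=genotypes,
    )
    truth = {"disease_alleles": disease, "bounds": truth_bounds, "seed": seed}
    return panel, truth


def write_flanking_panel(panel: FlankingPanel, path: str | Path) -> None:
    """Write a panel as the marker-panel TSV read by the haplotype module."""
    samples = list(panel.genotypes)
    with open(path, "w") as fh:
        fh.write("position\tref\talt\t" + "\t".join(samples) + "\n")
        for i, pos in enumerate(panel.positions):
            calls = "\t".join(
                "NA" if panel.genotypes[s][i] is GenotypeCall.MISSING
                else str(panel.genotypes[s][i].value)
                for s in samples
            )
            fh.write(f"{pos}\t{panel.refs[i]}\t{panel.alts[i]}\t{calls}\n")
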