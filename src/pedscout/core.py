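"""Domain types and file readers/writers shared by every pipeline stage.

Coordinate conventions used throughout the package:

* VCF records, marker positions and segment bounds are 1-based.
* BED output is 0-based, half-open.
* All physical lengths are computed as ``end - start`` on 1-based
  coordinates (no ``+1``); segment sizes in Mb and spans in kb derive
  from that difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from ._util import chrom_sort_key

log = logging.getLogger(__name__)


class GenotypeCall(Enum):
    """Unphased diploid genotype state for one sample at one biallelic site."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


class Role(Enum):
    """Pedigree/phenotype assignment driving the segregation filter."""

    CASE = "CASE"
    OBLIGATE_CARRIER = "OBLIGATE_CARRIER"
    UNAFFECTED = "UNAFFECTED"
    PANEL_CONTROL = "PANEL_CONTROL"


#: Sequence Ontology consequence terms ordered from most to least severe.
#: Used to pick a single representative consequence when an annotation
#: source reports one term per transcript.
SO_SEVERITY_ORDER: tuple[str, ...] = (
    "transcript_ablation",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
    "splice_region_variant",
    "incomplete_terminal_codon_variant",
    "start_retained_variant",
    "stop_retained_variant",
    "synonymous_variant",
    "coding_sequence_variant",
    "mature_miRNA_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "NMD_transcript_variant",
    "non_coding_transcript_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "TFBS_ablation",
    "TFBS_amplification",
    "TF_binding_site_variant",
    "regulatory_region_ablation",
    "regulatory_region_amplification",
    "feature_elongation",
    "regulatory_region_variant",
    "feature_truncation",
    "intergenic_variant",
)

_SEVERITY_RANK = {term: i for i, term in enumerate(SO_SEVERITY_ORDER)}


def most_severe(terms: Iterable[str]) -> str:
    """Return the most severe Sequence Ontology term among ``terms``.

    Unknown terms rank below every known one; ties between unknown terms
    break alphabetically so the choice is deterministic.
    """
    terms = list(terms)
    if not terms:
        raise ValueError("no consequence terms supplied")
    return min(terms, key=lambda t: (_SEVERITY_RANK.get(t, len(_SEVERITY_RANK)), t))


@dataclass
class Variant:
    """One biallelic site with per-sample genotype calls.

    Multi-allelic VCF records are decomposed on read into one ``Variant``
    per alternate allele. A sample whose genotype refers to a *different*
    alternate allele is recorded in ``other_alt_samples`` and its state set
    to HOM_REF: for the purposes of a biallelic recessive analysis it does
    not carry this allele.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    other_alt_samples: frozenset[str] = frozenset()
    info: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleRole:
    sample_id: str
    role: Role
    breed: str | None = None


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic span, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end for {self.name}")


@dataclass(frozen=True)
class Interval:
    """A bare genomic interval (1-based inclusive), e.g. a shared-ROH slice."""

    chrom: str
    start: int
    end: int


@dataclass
class MarkerGrid:
    """Ordered biallelic genotype calls along one chromosome.

    ``genotypes`` maps sample id to an int8 array aligned with
    ``positions`` using GenotypeCall values (0/1/2, -1 for missing).
    """

    chrom: str
    positions: np.ndarray
    genotypes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError(
                f"marker positions on {self.chrom} must be strictly increasing"
            )
        for sample, calls in self.genotypes.items():
            arr = np.asarray(calls, dtype=np.int8)
            if arr.shape != self.positions.shape:
                raise ValueError(
                    f"sample {sample} has {arr.size} calls for "
                    f"{self.positions.size} positions on {self.chrom}"
                )
            self.genotypes[sample] = arr

    @property
    def n_snps(self) -> int:
        return int(self.positions.size)

    @property
    def samples(self) -> list[str]:
        return list(self.genotypes)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


class VcfParseError(ValueError):
    pass


def _decode_gt(gt: tuple | None, alt_index: int) -> tuple[GenotypeCall, bool]:
    """Map a pysam GT tuple to a state for one alternate allele.

    Returns (state, refers_to_other_alt). Phase is ignored.
    """
    if gt is None or any(a is None for a in gt):
        return GenotypeCall.MISSING, False
    dose = sum(1 for a in gt if a == alt_index)
    if dose == 2:
        return GenotypeCall.HOM_ALT, False
    if dose == 1:
        return GenotypeCall.HET, False
    other = any(a not in (0, alt_index) for a in gt)
    return GenotypeCall.HOM_REF, other


def _csq_consequences(record, alt: str, csq_format: list[str]) -> list[str]:
    """Pull per-transcript consequence terms for one alt from a VEP CSQ field."""
    try:
        entries = record.info["CSQ"]
    except KeyError:
        return []
    if isinstance(entries, str):
        entries = (entries,)
    i_allele = csq_format.index("Allele") if "Allele" in csq_format else None
    i_cons = csq_format.index("Consequence")
    terms: list[str] = []
    for entry in entries:
        fields = entry.split("|")
        if i_allele is not None and len(fields) > i_allele:
            if fields[i_allele] not in (alt, ""):
                continue
        if len(fields) > i_cons and fields[i_cons]:
            terms.extend(fields[i_cons].split("&"))
    return terms


def read_vcf(path: str | Path, dialect: str = "effect") -> list[Variant]:
    """Read a VCF into a list of biallelic :class:`Variant` records.

    Parameters
    ----------
    path:
        A VCF 4.x file with a GT FORMAT field (plain text or bgzipped).
    dialect:
        Where the functional consequence comes from: ``"effect"`` reads a
        plain ``EFFECT`` INFO key holding Sequence Ontology terms (comma or
        ``&`` separated); ``"vep"`` parses a VEP ``CSQ`` INFO field. In both
        cases the most severe term wins. ``"none"`` leaves the consequence
        empty (marker-grid VCFs carry no annotation).

    Multi-allelic records are split into one Variant per alternate allele.
    """
    if dialect not in ("effect", "vep", "none"):
        raise ValueError(
            f"unknown annotation dialect {dialect!r}; expected 'effect', 'vep' or 'none'"
        )
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot read VCF {path}: {exc}") from exc

    csq_format: list[str] = []
    if dialect == "vep":
        try:
            desc = vcf.header.info["CSQ"].description
            csq_format = desc.split("Format:")[1].strip().split("|")
        except (KeyError, IndexError) as exc:
            raise VcfParseError(
                f"{path}: dialect 'vep' requires a CSQ INFO header with a Format description"
            ) from exc

    samples = list(vcf.header.samples)
    variants: list[Variant] = []
    for record in vcf:
        if record.alts is None:
            continue
        for alt_index, alt in enumerate(record.alts, start=1):
            genotypes: dict[str, GenotypeCall] = {}
            other: set[str] = set()
            for sample in samples:
                fmt = record.samples[sample]
                gt = fmt.get("GT") if "GT" in fmt else None
                state, is_other = _decode_gt(gt, alt_index)
                genotypes[sample] = state
                if is_other:
                    other.add(sample)
            if dialect == "effect":
                raw = record.info.get("EFFECT", "")
                if isinstance(raw, tuple):
                    raw = ",".join(raw)
                terms = [t for part in str(raw).split(",") for t in part.split("&") if t]
            elif dialect == "vep":
                terms = _csq_consequences(record, alt, csq_format)
            else:
                terms = []
            consequence = most_severe(terms) if terms else ""
            variants.append(
                Variant(
                    chrom=str(record.chrom),
                    pos=record.pos,
                    ref=record.ref,
                    alt=alt,
                    consequence=consequence,
                    genotypes=genotypes,
                    other_alt_samples=frozenset(other),
                )
            )
    return variants


def write_vcf(
    variants: Sequence[Variant],
    samples: Sequence[str],
    path: str | Path,
    contigs: Sequence[str] | None = None,
) -> None:
    """Write biallelic variants (one record each) as a minimal VCF 4.2 file."""
    if contigs is None:
        contigs = sorted({v.chrom for v in variants}, key=chrom_sort_key)
    gt_for = {
        GenotypeCall.HOM_REF: "0/0",
        GenotypeCall.HET: "0/1",
        GenotypeCall.HOM_ALT: "1/1",
        GenotypeCall.MISSING: "./.",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            '##INFO=<ID=EFFECT,Number=.,Type=String,'
            'Description="Functional consequence (Sequence Ontology)">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        for v in sorted(variants, key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.alt)):
            info = f"EFFECT={v.consequence}" if v.consequence else "."
            calls = "\t".join(
                gt_for[v.genotypes.get(s, GenotypeCall.MISSING)] for s in samples
            )
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t{info}\tGT\t{calls}\n"
            )


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def read_pedigree(path: str | Path) -> list[SampleRole]:
    """Read a whitespace-delimited pedigree/phenotype table.

    Columns: ``sample_id  role  [breed]``. Lines starting with ``#`` are
    comments. Roles must come from the controlled vocabulary; duplicate
    sample ids are rejected; at least one CASE must be present.
    """
    valid = {r.value for r in Role}
    roles: list[SampleRole] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'sample_id role [breed]'")
            sample_id, role_token = parts[0], parts[1]
            if role_token not in valid:
                raise ValueError(
                    f"{path}:{lineno}: unknown role {role_token!r}; "
                    f"valid roles: {sorted(valid)}"
                )
            if sample_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate sample id {sample_id!r}")
            seen.add(sample_id)
            breed = parts[2] if len(parts) > 2 else None
            roles.append(SampleRole(sample_id, Role(role_token), breed))
    if not any(r.role is Role.CASE for r in roles):
        raise ValueError(f"{path}: pedigree contains no CASE sample")
    return roles


# ---------------------------------------------------------------------------
# Marker grids
# ---------------------------------------------------------------------------


def read_marker_grid(path: str | Path) -> list[MarkerGrid]:
    """Read SNP-array-like genotypes into one :class:`MarkerGrid` per chromosome.

    Two formats are accepted:

    * a VCF restricted to biallelic SNVs (``.vcf``/``.vcf.gz``); records that
      are not biallelic SNVs are dropped with a logged count;
    * a grid TSV with header ``chrom  pos  <sample> ...`` and genotype codes
      0/1/2 (ref-hom/het/alt-hom) or ``NA``/``.`` for missing.

    Positions are sorted within each chromosome; duplicate positions are an
    error.
    """
    path = Path(path)
    if path.name.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _grid_from_vcf(path)
    return _grid_from_tsv(path)


_STATE_CODE = {"0": 0, "1": 1, "2": 2, "NA": -1, ".": -1, "-1": -1}


def _grid_from_tsv(path: Path) -> list[MarkerGrid]:
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 3 or header[:2] != ["chrom", "pos"]:
            raise ValueError(f"{path}: expected header 'chrom pos <samples...>'")
        samples = header[2:]
        per_chrom: dict[str, list[tuple[int, list[int]]]] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 2 + len(samples):
                raise ValueError(f"{path}:{lineno}: wrong column count")
            try:
                codes = [_STATE_CODE[c] for c in parts[2:]]
            except KeyError as exc:
                raise ValueError(f"{path}:{lineno}: bad genotype code {exc}") from exc
            per_chrom.setdefault(parts[0], []).append((int(parts[1]), codes))
    return _assemble_grids(per_chrom, samples, str(path))


def _grid_from_vcf(path: Path) -> list[MarkerGrid]:
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    per_chrom: dict[str, list[tuple[int, list[int]]]] = {}
    n_dropped = 0
    for record in vcf:
        alts = record.alts or ()
        if len(alts) != 1 or len(record.ref) != 1 or len(alts[0]) != 1:
            n_dropped += 1
            continue
        codes = []
        for sample in samples:
            gt = record.samples[sample].get("GT")
            state, _ = _decode_gt(gt, 1)
            codes.append(state.value)
        per_chrom.setdefault(str(record.chrom), []).append((record.pos, codes))
    if n_dropped:
        log.info("read_marker_grid: dropped %d non-biallelic-SNV sites", n_dropped)
    return _assemble_grids(per_chrom, samples, str(path))


def _assemble_grids(
    per_chrom: Mapping[str, list[tuple[int, list[int]]]],
    samples: list[str],
    source: str,
) -> list[MarkerGrid]:
    grids = []
    for chrom in sorted(per_chrom, key=chrom_sort_key):
        rows = sorted(per_chrom[chrom], key=lambda r: r[0])
        positions = np.array([r[0] for r in rows], dtype=np.int64)
        if np.any(np.diff(positions) == 0):
            raise ValueError(f"{source}: duplicate marker positions on {chrom}")
        matrix = np.array([r[1] for r in rows], dtype=np.int8)
        genotypes = {s: matrix[:, j].copy() for j, s in enumerate(samples)}
        grids.append(MarkerGrid(chrom=chrom, positions=positions, genotypes=genotypes))
    return grids


def write_marker_grid(grids: Sequence[MarkerGrid], path: str | Path) -> None:
    """Write grids in the grid TSV format accepted by :func:`read_marker_grid`."""
    if not grids:
        raise ValueError("no grids to write")
    samples = grids[0].samples
    with open(path, "w") as fh:
        fh.write("chrom\tpos\t" + "\t".join(samples) + "\n")
        for grid in sorted(grids, key=lambda g: chrom_sort_key(g.chrom)):
            if grid.samples != samples:
                raise ValueError("all grids must share the same sample set")
            cols = [grid.genotypes[s] for s in samples]
            for i, pos in enumerate(grid.positions):
                codes = "\t".join(
                    "NA" if col[i] == -1 else str(int(col[i])) for col in cols
                )
                fh.write(f"{grid.chrom}\t{int(pos)}\t{codes}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(intervals: Iterable, path: str | Path, name_field: str | None = None) -> None:
    """Write intervals (anything with chrom/start/end, 1-based inclusive) as BED.

    Output is 0-based half-open, sorted by (chrom, start). An optional
    attribute named by ``name_field`` becomes the BED name column.
    """
    rows = sorted(intervals, key=lambda x: (chrom_sort_key(x.chrom), x.start))
    with open(path, "w") as fh:
        if not rows:
            fh.write("# no intervals\n")
            return
        for item in rows:
            line = f"{item.chrom}\t{item.start - 1}\t{item.end}"
            if name_field is not None:
                line += f"\t{getattr(item, name_field)}"
            fh.write(line + "\n")


def read_bed(path: str | Path) -> list[GeneInterval]:
    """Read a BED file (0-based half-open) into 1-based GeneIntervals."""
    out: list[GeneInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            name = parts[3] if len(parts) > 3 else f"interval_{lineno}"
            out.append(
                GeneInterval(
                    chrom=parts[0], start=int(parts[1]) + 1, end=int(parts[2]), name=name
                )
            )
    return out
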