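"""Per-exon read-count summarization for qualitative tissue-expression calls.

The contract starts at per-exon aligned-read counts (read counting over
exon intervals is upstream). A gene is called EXPRESSED in the tissue when
its mean reads per exon exceeds the strongest non-expressed control by a
configurable factor — a deliberately qualitative measure, adequate for
establishing that a candidate gene is transcribed in the target tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from ._util import round_half_up


@dataclass
class ExonCounts:
    """Ordered per-exon aligned-read counts for one gene."""

    gene: str
    chrom: str
    start: int
    end: int
    exon_counts: list[int]

    def __post_init__(self) -> None:
        if not self.exon_counts:
            raise ValueError(f"{self.gene}: at least one exon is required")
        if any(c < 0 for c in self.exon_counts):
            raise ValueError(f"{self.gene}: exon counts must be non-negative")


@dataclass(frozen=True)
class GeneSummary:
    gene: str
    total_reads: int
    n_exons: int
    mean_raw: float

    @property
    def mean_reads_per_exon(self) -> int:
        """Mean reads per exon, rounded half-up to an integer for reporting."""
        return int(round_half_up(self.mean_raw))


def summarize_gene(counts: ExonCounts) -> GeneSummary:
    """Total aligned reads and mean reads per exon for one gene."""
    total = sum(counts.exon_counts)
    n = len(counts.exon_counts)
    return GeneSummary(gene=counts.gene, total_reads=total, n_exons=n, mean_raw=total / n)


def expression_call(
    summary: GeneSummary,
    expressed_control_means: Sequence[float],
    non_expressed_control_means: Sequence[float],
    factor: float = 2.0,
) -> str:
    """Call a gene EXPRESSED or NOT_DETECTED against control genes.

    EXPRESSED requires the gene's mean reads per exon to *strictly* exceed
    ``factor`` times the highest mean among non-expressed controls. Both
    control classes must be non-empty (the expressed controls anchor the
    qualitative comparison even though only the non-expressed maximum sets
    the threshold).
    """
    if not expressed_control_means or not non_expressed_control_means:
        raise ValueError("need at least one control gene in each class")
    threshold = factor * max(non_expressed_control_means)
    return "EXPRESSED" if summary.mean_raw > threshold else "NOT_DETECTED"


def gene_span_kb(start: int, end: int) -> int:
    """Gene span in kb, rounded half-up to the nearest integer."""
    if end <= start:
        raise ValueError(f"end ({end}) must exceed start ({start})")
    return int(round_half_up((end - start) / 1000))


def count_reads_in_exons(
    read_intervals: Sequence[tuple[str, int, int]],
    exons: Sequence[tuple[str, int, int]],
) -> list[int]:
    """Count read placements overlapping each exon by >= 1 bp.

    A tiny coverage helper for synthetic tests: ``read_intervals`` and
    ``exons`` are (chrom, start, end) on 1-based inclusive coordinates.
    """
    counts = []
    for chrom, start, end in exons:
        counts.append(
            sum(
                1
                for rc, rs, re in read_intervals
                if rc == chrom and rs <= end and start <= re
            )
        )
    return counts


def read_exon_table(path: str | Path) -> list[ExonCounts]:
    """Read a per-exon count TSV: gene, chrom, start, end, exon_index, read_count."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end", "exon_index", "read_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: columns must include {sorted(required)}")
    genes: list[ExonCounts] = []
    for gene, group in df.groupby("gene", sort=True):
        group = group.sort_values("exon_index")
        genes.append(
            ExonCounts(
                gene=str(gene),
                chrom=str(group["chrom"].iloc[0]),
                start=int(group["start"].iloc[0]),
                end=int(group["end"].iloc[0]),
                exon_counts=[int(c) for c in group["read_count"]],
            )
        )
    return genes


def expression_table(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    """Shape gene summaries as a report table (total and mean reads per exon)."""
    return pd.DataFrame(
        {
            "gene": [s.gene for s in summaries],
            "total_reads": [s.total_reads for s in summaries],
            "n_exons": [s.n_exons for s in summaries],
            "mean_reads_per_exon": [s.mean_reads_per_exon for s in summaries],
        }
    )
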