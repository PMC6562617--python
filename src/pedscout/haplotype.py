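"""Shared-haplotype extent around a candidate variant from unphased genotypes.

A panel of flanking markers is chosen to tag the disease haplotype: at each
marker the disease allele is the allele carried homozygously by all cases.
For any carrier, the extent of sharing is found by walking outward from the
candidate variant; a marker remains consistent with carriage of the disease
haplotype as long as the carrier's unphased genotype contains the disease
allele. Because phase is unknown, this is deliberately permissive: the
reported extent is an upper bound on true identity-by-descent sharing, which
is sufficient to compare sharing qualitatively across carriers and breeds
(nested, progressively shorter shared regions indicate an older haplotype).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import GenotypeCall

_CONTAINS = {
    "alt": (GenotypeCall.HET, GenotypeCall.HOM_ALT),
    "ref": (GenotypeCall.HET, GenotypeCall.HOM_REF),
}


@dataclass
class FlankingPanel:
    """Ordered markers flanking (and including) the candidate variant."""

    positions: list[int]
    refs: list[str]
    alts: list[str]
    candidate_index: int
    genotypes: dict[str, list[GenotypeCall]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.positions)
        if sorted(self.positions) != self.positions or len(set(self.positions)) != n:
            raise ValueError("marker positions must be strictly increasing")
        if not 0 <= self.candidate_index < n:
            raise ValueError("candidate_index out of range")
        if len(self.refs) != n or len(self.alts) != n:
            raise ValueError("refs/alts must align with positions")
        for sample, calls in self.genotypes.items():
            if len(calls) != n:
                raise ValueError(f"sample {sample} has {len(calls)} calls for {n} markers")

    @property
    def candidate_position(self) -> int:
        return self.positions[self.candidate_index]


@dataclass(frozen=True)
class HaplotypeExtent:
    """Furthest marker positions consistent with disease-haplotype carriage."""

    sample_id: str
    left_bound: int
    right_bound: int

    def __post_init__(self) -> None:
        if self.left_bound > self.right_bound:
            raise ValueError("left_bound must not exceed right_bound")

    @property
    def length(self) -> int:
        return self.right_bound - self.left_bound

    @property
    def length_kb(self) -> float:
        return self.length / 1000


def disease_alleles(panel: FlankingPanel, cases: Sequence[str]) -> list[str | None]:
    """Per-marker disease-haplotype allele: 'ref', 'alt', or None (uninformative).

    The disease allele at a marker is the allele homozygous in *all* cases;
    markers where any case is heterozygous, missing, or where cases disagree
    are uninformative. Every case must be HOM_ALT at the candidate itself.
    """
    if not cases:
        raise ValueError("at least one case sample is required")
    for case in cases:
        if case not in panel.genotypes:
            raise KeyError(f"case {case!r} not genotyped in panel")
        if panel.genotypes[case][panel.candidate_index] is not GenotypeCall.HOM_ALT:
            raise ValueError(
                f"case {case!r} is not homozygous-alternate at the candidate variant"
            )
    alleles: list[str | None] = []
    for i in range(len(panel.positions)):
        states = {panel.genotypes[c][i] for c in cases}
        if states == {GenotypeCall.HOM_ALT}:
            alleles.append("alt")
        elif states == {GenotypeCall.HOM_REF}:
            alleles.append("ref")
        else:
            alleles.append(None)
    return alleles


def carrier_extent(
    panel: FlankingPanel,
    alleles: Sequence[str | None],
    sample_id: str,
) -> HaplotypeExtent:
    """Extent of disease-haplotype sharing for one carrier.

    Walk outward from the candidate in each direction; stop at the first
    marker that is uninformative or whose genotype lacks the disease allele
    (missing calls also stop the walk). Bounds default to the candidate
    position itself when the nearest flanking marker is already
    inconsistent.
    """
    calls = panel.genotypes.get(sample_id)
    if calls is None:
        raise KeyError(f"sample {sample_id!r} not genotyped in panel")
    ci = panel.candidate_index
    if calls[ci] not in (GenotypeCall.HET, GenotypeCall.HOM_ALT):
        raise ValueError(
            f"sample {sample_id!r} does not carry the disease allele at the candidate"
        )

    def consistent(i: int) -> bool:
        allele = alleles[i]
        return allele is not None and calls[i] in _CONTAINS[allele]

    left = ci
    while left > 0 and consistent(left - 1):
        left -= 1
    right = ci
    while right < len(alleles) - 1 and consistent(right + 1):
        right += 1
    return HaplotypeExtent(
        sample_id=sample_id,
        left_bound=panel.positions[left],
        right_bound=panel.positions[right],
    )


def read_flanking_panel(path: str | Path, candidate_position: int) -> FlankingPanel:
    """Read a marker-panel TSV: position, ref, alt, then one column per sample.

    Genotype tokens: 0/1/2 or NA. The candidate variant must be one of the
    rows (matched by position).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("position", "ref", "alt"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    df = df.assign(position=df["position"].astype(int)).sort_values("position")
    positions = df["position"].tolist()
    if candidate_position not in positions:
        raise ValueError(f"{path}: candidate position {candidate_position} not in panel")
    code = {"0": GenotypeCall.HOM_REF, "1": GenotypeCall.HET, "2": GenotypeCall.HOM_ALT,
            "NA": GenotypeCall.MISSING, ".": GenotypeCall.MISSING}
    samples = [c for c in df.columns if c not in ("position", "ref", "alt")]
    genotypes = {s: [code[t] for t in df[s]] for s in samples}
    return FlankingPanel(
        positions=positions,
        refs=df["ref"].tolist(),
        alts=df["alt"].tolist(),
        candidate_index=positions.index(candidate_position),
        genotypes=genotypes,
    )


def extents_table(extents: Sequence[HaplotypeExtent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in extents],
            "left_bound": [e.left_bound for e in extents],
            "right_bound": [e.right_bound for e in extents],
            "length_kb": [e.length_kb for e in extents],
        }
    )
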