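"""Recessive-variant prioritization funnel.

The funnel mirrors a standard small-pedigree discovery design: annotate
each variant with an effect tier, keep those compatible with autosomal
recessive segregation in the sequenced family, then subtract variants seen
in successive panels of control genomes. Counts surviving each stage are
reported so the analyst can see where candidates are lost.

Note on the segregation model: affected samples must be homozygous for the
alternate allele and obligate-carrier parents heterozygous. Unaffected
family members are required only to NOT be homozygous-alternate — an
unaffected sibling may well be a heterozygous carrier under a recessive
model, so heterozygosity does not disqualify a variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

from .core import GenotypeCall, Role, SampleRole, Variant

log = logging.getLogger(__name__)

#: Consequence terms treated as protein-changing ("high effect") by default:
#: loss/gain of start and stop codons, essential splice-site disruption,
#: missense substitutions, frameshifts and in-frame deletions.
DEFAULT_HIGH_EFFECT_TERMS: frozenset[str] = frozenset(
    {
        "start_lost",
        "stop_gained",
        "stop_lost",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "missense_variant",
        "frameshift_variant",
        "inframe_deletion",
    }
)


@dataclass(frozen=True)
class EffectTier:
    """Partition of the consequence vocabulary into HIGH and LOW tiers."""

    high_terms: frozenset[str] = DEFAULT_HIGH_EFFECT_TERMS

    def __post_init__(self) -> None:
        missing = DEFAULT_HIGH_EFFECT_TERMS - self.high_terms
        if missing:
            raise ValueError(
                f"high tier must contain the core protein-changing terms; missing {sorted(missing)}"
            )


@dataclass(frozen=True)
class PanelPolicy:
    """Carrier tolerance for one control panel.

    ``max_het_carriers`` heterozygotes and ``max_hom_alt`` homozygous-alternate
    samples are tolerated among PANEL_CONTROL genomes before a variant is
    excluded.
    """

    max_het_carriers: int = 0
    max_hom_alt: int = 0

    def __post_init__(self) -> None:
        if self.max_het_carriers < 0 or self.max_hom_alt < 0:
            raise ValueError("panel thresholds must be non-negative")


@dataclass
class FunnelReport:
    """Surviving-variant counts per filtering stage, in application order."""

    stages: list[tuple[str, int]] = field(default_factory=list)

    def add(self, label: str, count: int) -> None:
        if self.stages and count > self.stages[-1][1]:
            raise ValueError(
                f"funnel counts must be non-increasing: stage {label!r} has "
                f"{count} > previous {self.stages[-1][1]}"
            )
        self.stages.append((label, count))

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.stages]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for label, count in self.stages:
                fh.write(f"{label}\t{count}\n")


def classify_effect(variant: Variant, tiers: EffectTier | None = None) -> str:
    """Classify a variant's consequence as ``"HIGH"`` or ``"LOW"``.

    Terms outside the known vocabulary fall to LOW with a logged warning.
    """
    tiers = tiers or EffectTier()
    term = variant.consequence
    if term in tiers.high_terms:
        return "HIGH"
    from .core import _SEVERITY_RANK  # known-vocabulary check only

    if term and term not in _SEVERITY_RANK:
        log.warning("unknown consequence term %r at %s:%d -> LOW", term, variant.chrom, variant.pos)
    return "LOW"


MissingPolicy = Literal["strict", "lenient"]


def segregates(
    variant: Variant,
    roles: Sequence[SampleRole],
    missing_policy: MissingPolicy = "strict",
) -> bool:
    """Does one variant fit autosomal recessive segregation in the family?

    CASE samples must be HOM_ALT, OBLIGATE_CARRIER samples HET, and
    UNAFFECTED samples anything but HOM_ALT. PANEL_CONTROL samples are
    ignored here (they are handled by :func:`panel_filter`). Under the
    default strict policy a MISSING call in any family member fails the
    variant; the lenient policy skips MISSING calls.
    """
    for sr in roles:
        if sr.role is Role.PANEL_CONTROL:
            continue
        state = variant.genotypes.get(sr.sample_id, GenotypeCall.MISSING)
        if state is GenotypeCall.MISSING:
            if missing_policy == "strict":
                return False
            continue
        if sr.role is Role.CASE and state is not GenotypeCall.HOM_ALT:
            return False
        if sr.role is Role.OBLIGATE_CARRIER and state is not GenotypeCall.HET:
            return False
        if sr.role is Role.UNAFFECTED and state is GenotypeCall.HOM_ALT:
            return False
    return True


def segregation_filter(
    variants: Sequence[Variant],
    roles: Sequence[SampleRole],
    missing_policy: MissingPolicy = "strict",
    autosomes_only: bool = False,
    autosome_labels: frozenset[str] | None = None,
) -> list[Variant]:
    """Retain variants compatible with the recessive model in the family."""
    if not any(r.role is Role.CASE for r in roles):
        raise ValueError("segregation filter requires at least one CASE sample")
    kept = []
    for v in variants:
        if autosomes_only and autosome_labels is not None and v.chrom not in autosome_labels:
            continue
        if segregates(v, roles, missing_policy):
            kept.append(v)
    return kept


def panel_carrier_counts(
    variant: Variant,
    panel_genotypes: Mapping[tuple, Mapping[str, GenotypeCall]],
) -> tuple[int, int]:
    """Count (het, hom_alt) carriers of ``variant`` among panel genomes.

    ``panel_genotypes`` maps a variant key (chrom, pos, ref, alt) to the
    panel's per-sample calls. A variant absent from the panel has zero
    carriers there.
    """
    calls = panel_genotypes.get(variant.key, {})
    n_het = sum(1 for s in calls.values() if s is GenotypeCall.HET)
    n_hom = sum(1 for s in calls.values() if s is GenotypeCall.HOM_ALT)
    return n_het, n_hom


def panel_lookup(panel_variants: Sequence[Variant]) -> dict[tuple, dict[str, GenotypeCall]]:
    """Index a panel VCF's variants by (chrom, pos, ref, alt) for carrier counting."""
    return {v.key: v.genotypes for v in panel_variants}


def panel_filter(
    variants: Sequence[Variant],
    panel_genotypes: Mapping[tuple, Mapping[str, GenotypeCall]],
    policy: PanelPolicy,
) -> list[Variant]:
    """Retain variants whose panel carrier counts are within policy limits."""
    kept = []
    for v in variants:
        n_het, n_hom = panel_carrier_counts(v, panel_genotypes)
        if n_het <= policy.max_het_carriers and n_hom <= policy.max_hom_alt:
            kept.append(v)
    return kept


def run_funnel(
    variants: Sequence[Variant],
    roles: Sequence[SampleRole],
    tiers: EffectTier | None = None,
    panels: Sequence[Mapping[tuple, Mapping[str, GenotypeCall]]] = (),
    policies: Sequence[PanelPolicy] = (),
    panel_labels: Sequence[str] | None = None,
    missing_policy: MissingPolicy = "strict",
) -> tuple[list[Variant], FunnelReport]:
    """Run the full prioritization funnel and return candidates plus counts.

    Stages, in order: all input variants; HIGH-effect variants; those also
    segregating recessively in the family; then one stage per control panel
    applied sequentially with its own :class:`PanelPolicy`.
    """
    if len(panels) != len(policies):
        raise ValueError("need exactly one PanelPolicy per panel")
    tiers = tiers or EffectTier()
    labels = list(panel_labels) if panel_labels is not None else [
        f"panel_{i + 1}" for i in range(len(panels))
    ]
    if len(labels) != len(panels):
        raise ValueError("need exactly one label per panel")

    report = FunnelReport()
    report.add("all", len(variants))

    survivors = [v for v in variants if classify_effect(v, tiers) == "HIGH"]
    report.add("high_effect", len(survivors))

    survivors = segregation_filter(survivors, roles, missing_policy)
    report.add("segregating", len(survivors))

    for panel, policy, label in zip(panels, policies, labels):
        survivors = panel_filter(survivors, panel, policy)
        report.add(label, len(survivors))

    from ._util import chrom_sort_key

    survivors.sort(key=lambda v: (chrom_sort_key(v.chrom), v.pos, v.alt))
    return survivors, report
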