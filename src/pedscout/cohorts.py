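"""Per-breed genotype counting and allele-frequency estimation.

The allele frequency of a biallelic variant in a cohort is the alternate
allele count over the number of chromosomes genotyped:

    f = (n_het + 2 * n_hom_alt) / (2 * N),   N = n_hom_ref + n_het + n_hom_alt

Only successfully genotyped dogs enter the denominator; mixed-breed or
unknown-breed dogs are excluded from breed-specific frequencies but still
appear in the homozygote census. Relatedness is supplied as an explicit
sample list (known pedigree relatives of the probands); no kinship is
inferred.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import round_half_up
from .core import GenotypeCall

log = logging.getLogger(__name__)

#: breed labels treated as non-breed-specific in frequency tables
NON_BREED_LABELS = frozenset({"mixed", "unknown", "crossbreed", "cross-breed"})

_GENO_TOKEN = {
    "0": GenotypeCall.HOM_REF,
    "1": GenotypeCall.HET,
    "2": GenotypeCall.HOM_ALT,
    "REF": GenotypeCall.HOM_REF,
    "HET": GenotypeCall.HET,
    "ALT": GenotypeCall.HOM_ALT,
    "NA": GenotypeCall.MISSING,
    ".": GenotypeCall.MISSING,
}


@dataclass(frozen=True)
class CohortCounts:
    """Genotype counts for one breed cohort at one variant."""

    breed: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    exclude_related: bool = False

    def __post_init__(self) -> None:
        if min(self.n_hom_ref, self.n_het, self.n_hom_alt) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


def allele_frequency(counts: CohortCounts) -> float:
    """Raw alternate allele frequency (het + 2*hom_alt) / (2*total)."""
    if counts.total == 0:
        raise ValueError(f"cohort {counts.breed!r} has no genotyped samples")
    return (counts.n_het + 2 * counts.n_hom_alt) / (2 * counts.total)


def reported_frequency(counts: CohortCounts, ndigits: int = 3) -> float:
    """Allele frequency rounded half-up for table output (default 3 decimals)."""
    return round_half_up(allele_frequency(counts), ndigits)


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of per-sample calls: sample_id, breed, genotype[, role].

    Genotype tokens may be 0/1/2 or REF/HET/ALT; NA/. mark failed assays.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "breed", "genotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: columns must include {sorted(required)}")
    bad = set(df["genotype"]) - set(_GENO_TOKEN)
    if bad:
        raise ValueError(f"{path}: unknown genotype tokens {sorted(bad)}")
    df = df.copy()
    df["call"] = df["genotype"].map(_GENO_TOKEN)
    return df


def tabulate_cohorts(
    table: pd.DataFrame,
    related_samples: Iterable[str] | None = None,
) -> list[CohortCounts]:
    """Aggregate a per-sample genotype table into per-breed counts.

    Samples with a MISSING call are dropped with a logged count. When a
    relatedness list is supplied, each breed containing listed samples gets
    a second record with those samples removed (``exclude_related=True``).
    """
    if "call" not in table.columns:
        table = table.assign(call=table["genotype"].map(_GENO_TOKEN))
    n_missing = int((table["call"] == GenotypeCall.MISSING).sum())
    if n_missing:
        log.info("tabulate_cohorts: dropped %d samples with failed genotypes", n_missing)
    table = table[table["call"] != GenotypeCall.MISSING]
    related = set(related_samples or ())

    out: list[CohortCounts] = []
    for breed, group in table.groupby("breed", sort=True):
        out.append(_count(breed, group, exclude_related=False))
        if related and group["sample_id"].isin(related).any():
            reduced = group[~group["sample_id"].isin(related)]
            out.append(_count(breed, reduced, exclude_related=True))
    return out


def _count(breed: str, group: pd.DataFrame, exclude_related: bool) -> CohortCounts:
    calls = group["call"]
    return CohortCounts(
        breed=breed,
        n_hom_ref=int((calls == GenotypeCall.HOM_REF).sum()),
        n_het=int((calls == GenotypeCall.HET).sum()),
        n_hom_alt=int((calls == GenotypeCall.HOM_ALT).sum()),
        exclude_related=exclude_related,
    )


def homozygote_census(table: pd.DataFrame) -> pd.DataFrame:
    """Every sample homozygous for the alternate allele, with breed (and role).

    Mixed/unknown-breed samples are included here even though they are
    excluded from breed-specific frequencies.
    """
    if "call" not in table.columns:
        table = table.assign(call=table["genotype"].map(_GENO_TOKEN))
    cols = [c for c in ("sample_id", "breed", "role") if c in table.columns]
    return table.loc[table["call"] == GenotypeCall.HOM_ALT, cols].reset_index(drop=True)


def frequency_table(
    cohorts: Sequence[CohortCounts], ndigits: int = 3
) -> pd.DataFrame:
    """Shape per-breed counts and rounded frequencies as a report table."""
    rows = []
    for c in cohorts:
        breed_specific = c.breed.lower() not in NON_BREED_LABELS
        rows.append(
            {
                "breed": c.breed + (" *" if c.exclude_related else ""),
                "n_hom_ref": c.n_hom_ref,
                "n_het": c.n_het,
                "n_hom_alt": c.n_hom_alt,
                "allele_frequency": reported_frequency(c, ndigits) if breed_specific else None,
            }
        )
    return pd.DataFrame(rows)
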