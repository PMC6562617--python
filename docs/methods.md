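# Methods

This document records the model implemented by `pedscout`, all parameter
defaults with units, the numerical conventions, the realism and limits of
the synthetic generators, and design rationale for the open choices. No
empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` actually compute.

## 1. Recessive segregation model

Samples carry roles: `CASE` (affected), `OBLIGATE_CARRIER` (parent of an
affected under the recessive model), `UNAFFECTED` (relative of unknown
carrier status), `PANEL_CONTROL`. A biallelic variant *segregates* when

- every `CASE` is homozygous-alternate (2),
- every `OBLIGATE_CARRIER` is heterozygous (1),
- no `UNAFFECTED` is homozygous-alternate.

Missing genotypes: `strict` (default) treats a missing call in any
constrained role as a violation; `lenient` ignores missing calls. Only
autosomes are considered by default.

Multi-allelic VCF records are decomposed per alternate allele; a sample
carrying a *different* alternate allele at the site is recorded as
homozygous-reference with respect to the allele under test and flagged in
`other_alt_samples`.

## 2. Effect tiers

The high-effect tier defaults to: `start_lost`, `stop_gained`,
`stop_lost`, `splice_acceptor_variant`, `splice_donor_variant`,
`missense_variant`, `frameshift_variant`, `inframe_deletion`. When a
record carries multiple consequence annotations (VEP `CSQ`), the most
severe by a fixed sequence-ontology order is used. Unknown consequence
terms classify as LOW with a logged warning rather than an error, so an
unexpected annotator vocabulary degrades conservatively.

## 3. Control-panel policies

For each panel, a variant's heterozygous-carrier and homozygous-alternate
counts are compared against a `PanelPolicy(max_het_carriers, max_hom_alt)`.
Defaults: zero tolerance on every panel, except the last panel tolerates
one heterozygous carrier (`max_het_carriers=1, max_hom_alt=0`) — a rare
founder allele may drift into related breeds as carriers without ever
appearing homozygous. The funnel report has one stage per filter in
application order — `all → high_effect → segregating → panel_1 → … →
panel_k` — and enforces non-increasing counts.

## 4. ROH detection

PLINK-style sliding-window scan per sample and chromosome. Parameter
defaults (units in names):

| parameter          | default | meaning                                              |
|--------------------|---------|------------------------------------------------------|
| `window_snp`       | 50      | markers per scanning window                          |
| `window_het`       | 1       | max heterozygous calls for a window to count         |
| `window_missing`   | 5       | max missing calls for a window to count              |
| `window_threshold` | 0.05    | min fraction of spanning windows that must be hom.   |
| `min_snp`          | 100     | min markers per emitted segment                      |
| `min_kb`           | 1000    | min segment length, kb                               |
| `density_kb`       | 50      | max kb per marker within a segment                   |
| `gap_kb`           | 1000    | split segments at inter-marker gaps above this, kb   |
| `window_kb`        | 5000    | recorded; not enforced unless `enforce_window_kb`    |

A window is *homozygous* when it contains ≤ `window_het` heterozygous and
≤ `window_missing` missing calls. Each marker's hit rate is the fraction
of windows spanning it that are homozygous, with the denominator clipped
near chromosome ends to the number of windows that actually exist
(end-correction). Markers with hit rate ≥ `window_threshold` are
in-state; maximal in-state runs are split at gaps > `gap_kb` and emitted
when they pass `min_snp`, `min_kb` and the density check. Segment bounds
are the first/last in-state marker (1-based, inclusive). `window_kb` is
accepted for completeness but not enforced by default, matching the
behaviour of the reference implementation of this algorithm.

The implementation is vectorized (convolution + cumulative sums); the
test suite proves it equivalent to a from-scratch exhaustive evaluation of
every window on >100 randomized grids with randomized parameters.

### Boundary behaviour

Window arithmetic makes exact base-pair recovery of an autozygosity
boundary impossible in principle. With defaults, a marker needs
≥ ceil(0.05·50) = 3 homozygous spanning windows to be in-state, so the
outermost 1–2 markers of a true block are never in-state; conversely the
detected edge can overshoot into a flank until two heterozygotes
accumulate (one is tolerated per window). The supported guarantee,
verified over 50 seeds, is: for a noise-free block in
heterozygote-saturated flanks, both detected edges lie within one
inter-marker spacing of the block's *marker footprint* (the first/last
grid marker inside the block). At realistic noise (25% flank
heterozygosity, 0.2% block heterozygosity, 1% missing) the tests assert
detection of every sufficiently large planted block and no spurious
segments in pure flanks, not base-level boundary accuracy.

### Segment algebra

Case-shared intervals are pairwise intersections of per-sample segments
(1-based inclusive). Parent exclusion removes a case-shared segment
entirely if it overlaps any parental ROH by ≥1 bp (segments that merely
abut survive). Gene annotation uses an interval tree over [start, end+1)
half-open coordinates. BED output is 0-based half-open; sizes in Mb are
(end − start)/10⁶ — no +1 — rounded to 2 decimals.

## 5. Allele frequencies

f = (het + 2·hom_alt) / (2N) over samples with non-missing genotypes;
reported values are rounded to 3 decimals. Cohort tables may carry a
second, relatives-excluded row per breed when a relatedness list is
supplied. Cohorts labelled `mixed`/`unknown`/`crossbreed` get no breed
frequency.

## 6. Haplotype extent

Flanking markers are tagged with the *disease allele*: the allele all
cases are homozygous for at that marker (markers where cases disagree or
are heterozygous are uninformative). A carrier's shared extent is the
maximal run of consecutive markers around the candidate at which the
carrier's unphased genotype *can contain* the disease allele; the walk
stops at the first inconsistent or uninformative marker, and bounds
default to the candidate position itself. Because genotypes are unphased,
this is a permissive upper bound on true identity-by-descent sharing.
Extent length is right − left in bp (reported also in kb).

## 7. Expression summary

Per gene: total reads, exon count, mean reads per exon (rounded to the
nearest integer, half-up). A gene is called `EXPRESSED` when its raw mean
strictly exceeds `factor` (default 2.0) times the maximum mean among
non-expressed control genes; both control sets must be non-empty. Gene
span in kb is (end − start)/1000 rounded half-up to an integer.

## 8. Numerical conventions

All reported rounding uses decimal half-up (`decimal.Decimal` with
`ROUND_HALF_UP`), not Python's default banker's rounding — several
reference frequencies (e.g. 9/618 = 0.01456… → 0.015) and the mean
reads per exon (93.625 → 94) depend on it. Coordinates are 1-based
inclusive internally, converted at the BED boundary only. All genotype
arrays are int8 with −1 for missing.

## 9. Synthetic generators: realism and limitations

All generators take a seed (`numpy.random.default_rng`) and emit truth
records; identical seeds give byte-identical outputs.

- **Quartet cohort** (`gen_quartet_cohort` / `gen_quartet_vcf`): one
  planted causal missense variant, and `n_background_variants` (default
  999) adversarial background variants assigned round-robin to
  categories that each violate exactly one filter (low effect, case not
  hom-alt, parent not het, unaffected hom-alt, present in panel 1,
  homozygous in panel 2). Panel sizes default to (112, 452). This makes
  funnel counts exactly predictable and stresses each filter
  independently; it does *not* model linkage, allele-frequency spectra,
  or realistic consequence proportions.
- **Marker grid** (`gen_marker_grid`): markers at jittered spacing
  (uniform 0.5–1.5 × `mean_spacing_bp`, default 20 kb), heterozygosity
  0.25 outside planted blocks, 0.002 inside, 1% missing. Markers are
  independent — no linkage disequilibrium — so the baseline cannot form
  long chance ROH, which real array data occasionally does.
- **Cohort table** (`gen_cohort_table`): deterministic expansion of
  genotype-count triples into per-sample rows; exact round-trip is a
  tested guarantee.
- **Flanking panel** (`gen_flanking_panel`): founder haplotype with
  breed-specific retained extents (Giant Schnauzer > Giant Spitz >
  Dachshund), markers within the bundled downstream/upstream flank
  distances of the candidate.
- **Exon counts** (`gen_exon_counts`): independent Poisson counts per
  exon at given rates; no exon-length or mappability effects.

Default problem sizes are package choices: genome-scale inputs (tens of
millions of variants, >100k array markers) are exercised structurally
(a >100k-marker multi-chromosome grid test) but the demo pipeline uses
~10³ variants and ~2×10³ markers so the full test suite runs in seconds.

## 10. Open design choices

- **Marker-grid format**: a single TSV (`chrom pos SAMPLE…`, calls
  0/1/2/NA) instead of a two-file map/genotype pair — self-describing,
  diff-able, directly readable by pandas; VCF is also accepted.
- **Funnel staging**: filters apply strictly sequentially with one
  report row per stage; joint formulations of segregation and panel
  membership would change intermediate counts but not the final
  candidate set, and the sequential form makes each stage's effect
  auditable.
- **Strict missing-genotype policy by default**: with only four family
  genomes a missing call in a constrained role removes most of the
  model's evidence, so conservatism is the safer default; `lenient` is
  available for sparse data.
- **Expression threshold as a parameter**: the 2× factor is a
  convention, not a fitted value; it is exposed (`factor`) rather than
  hard-coded.
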