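# Demo configuration for `pedscout run`: full pipeline on synthetic data.
#
# The quartet design mirrors the motivating study: two affected full
# siblings and both obligate-carrier parents sequenced, a first control
# panel of 112 genomes (zero tolerance) and a second of 452 genomes
# tolerating one heterozygous carrier. One causal missense variant is
# planted among 999 adversarial background variants.
seed: 7
outdir: demo_out

simulate:
  quartet:
    n_cases: 2
    n_unaffected_sibs: 0
    panel_sizes: [112, 452]
    n_background_variants: 999
  grid:
    chromosomes: {"27": 45000000}
    mean_spacing_bp: 20000
    baseline_het: 0.25
    blocks:
      CASE1: [["27", 36722004, 45000000]]
      CASE2: [["27", 36722004, 45000000]]

prioritize:
  dialect: effect
  missing_policy: strict
  policies:
    - {max_het_carriers: 0, max_hom_alt: 0}
    - {max_het_carriers: 1, max_hom_alt: 0}

roh:
  cases: [CASE1, CASE2]
  parents: [SIRE, DAM]
  params:
    window_snp: 50
    window_het: 1
    window_missing: 5
    window_threshold: 0.05
    min_snp: 100
    min_kb: 1000
    density_kb: 50
    gap_kb: 1000
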