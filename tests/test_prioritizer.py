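"""Effect tiers, recessive segregation, panel subtraction and the funnel."""

import numpy as np
import pytest

from pedscout.core import GenotypeCall, Role, SampleRole, Variant
from pedscout.prioritizer import (
    DEFAULT_HIGH_EFFECT_TERMS,
    EffectTier,
    FunnelReport,
    PanelPolicy,
    classify_effect,
    panel_filter,
    run_funnel,
    segregation_filter,
)

from helpers import make_variant


class TestEffectTier:
    @pytest.mark.parametrize(
        "term,tier",
        [
            ("missense_variant", "HIGH"),
            ("stop_gained", "HIGH"),
            ("frameshift_variant", "HIGH"),
            ("inframe_deletion", "HIGH"),
            ("splice_donor_variant", "HIGH"),
            ("synonymous_variant", "LOW"),
            ("intergenic_variant", "LOW"),
            ("intron_variant", "LOW"),
        ],
    )
    def test_classification(self, term, tier):
        assert classify_effect(make_variant("AAHHR", consequence=term)) == tier

    def test_unknown_term_is_low(self):
        assert classify_effect(make_variant("AAHHR", consequence="weird_term")) == "LOW"

    def test_tier_must_keep_core_terms(self):
        with pytest.raises(ValueError):
            EffectTier(high_terms=frozenset({"missense_variant"}))


class TestSegregation:
    def test_quartet_pattern_retained(self, quartet_roles):
        # cases hom-alt, parents het, sib het: the classic recessive pattern
        kept = segregation_filter([make_variant("AAHHH")], quartet_roles)
        assert len(kept) == 1

    @pytest.mark.parametrize(
        "states",
        ["HAHHR",  # a case is het
         "RAHHR",  # a case is hom-ref
         "AARHR",  # a parent is hom-ref (not an obligate carrier genotype)
         "AAAHR",  # a parent is hom-alt
         "AAHHA"],  # unaffected sib hom-alt violates the recessive model
    )
    def test_violations_rejected(self, states, quartet_roles):
        assert segregation_filter([make_variant(states)], quartet_roles) == []

    def test_unaffected_het_carrier_allowed(self, quartet_roles):
        # unaffected sibs may carry one copy under a recessive model
        assert len(segregation_filter([make_variant("AAHH R")], quartet_roles)) == 1

    def test_missing_policy(self, quartet_roles):
        v = make_variant("AAHHM")
        assert segregation_filter([v], quartet_roles, "strict") == []
        assert segregation_filter([v], quartet_roles, "lenient") == [v]

    def test_requires_a_case(self):
        roles = [SampleRole("X", Role.UNAFFECTED)]
        with pytest.raises(ValueError, match="CASE"):
            segregation_filter([make_variant("R")], roles)


class TestPanelFilter:
    def _panel(self, states):
        calls = {
            f"P{i}": {"H": GenotypeCall.HET, "A": GenotypeCall.HOM_ALT,
                      "R": GenotypeCall.HOM_REF}[c]
            for i, c in enumerate(states)
        }
        return {("27", 37_468_611, "G", "A"): calls}

    def test_clean_variant_retained_under_zero_tolerance(self):
        v = make_variant("AAHHR")
        assert panel_filter([v], self._panel("RRRR"), PanelPolicy(0, 0)) == [v]

    def test_one_het_carrier_tolerated_by_policy(self):
        v = make_variant("AAHHR")
        panel = self._panel("HRRR")
        assert panel_filter([v], panel, PanelPolicy(max_het_carriers=1)) == [v]
        assert panel_filter([v], panel, PanelPolicy(max_het_carriers=0)) == []

    def test_hom_alt_in_panel_rejected(self):
        v = make_variant("AAHHR")
        assert panel_filter([v], self._panel("ARRR"), PanelPolicy(5, 0)) == []

    def test_variant_absent_from_panel_has_no_carriers(self):
        v = make_variant("AAHHR", pos=999)
        assert panel_filter([v], self._panel("AAAA"), PanelPolicy(0, 0)) == [v]


class TestFunnelReport:
    def test_non_increasing_enforced(self):
        report = FunnelReport()
        report.add("all", 10)
        report.add("next", 10)
        with pytest.raises(ValueError, match="non-increasing"):
            report.add("bad", 11)

    def test_tsv_shape(self, tmp_path):
        report = FunnelReport()
        for label, n in [("all", 5), ("high_effect", 3), ("segregating", 1)]:
            report.add(label, n)
        path = tmp_path / "funnel.tsv"
        report.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0] == "stage\tcount"
        assert lines[1:] == ["all\t5", "high_effect\t3", "segregating\t1"]


def _random_cohort(seed, n_variants=150, n_panel=6):
    """Arbitrary genotype grid: variants need not follow any design."""
    rng = np.random.default_rng(seed)
    family = ["CASE1", "CASE2", "SIRE", "DAM", "SIB1"]
    panel = [f"P{i}" for i in range(n_panel)]
    roles = [
        SampleRole("CASE1", Role.CASE), SampleRole("CASE2", Role.CASE),
        SampleRole("SIRE", Role.OBLIGATE_CARRIER), SampleRole("DAM", Role.OBLIGATE_CARRIER),
        SampleRole("SIB1", Role.UNAFFECTED),
    ]
    terms = ["missense_variant", "stop_gained", "synonymous_variant",
             "intron_variant", "frameshift_variant", "intergenic_variant"]
    states = [GenotypeCall.HOM_REF, GenotypeCall.HET, GenotypeCall.HOM_ALT,
              GenotypeCall.MISSING]
    variants, panel_map = [], {}
    for i in range(n_variants):
        v = Variant(
            chrom=str(rng.integers(1, 5)), pos=int(1000 + i), ref="G", alt="A",
            consequence=terms[rng.integers(len(terms))],
            genotypes={s: states[rng.integers(4)] for s in family},
        )
        variants.append(v)
        panel_map[v.key] = {s: states[rng.integers(3)] for s in panel}
    return variants, roles, panel_map


def _oracle_survivors(variants, roles, panel_map, policy, missing_policy="strict"):
    """Brute-force per-variant re-evaluation of the three funnel predicates."""
    high = DEFAULT_HIGH_EFFECT_TERMS
    by_role = {}
    for r in roles:
        by_role.setdefault(r.role, []).append(r.sample_id)
    out = []
    for v in variants:
        if v.consequence not in high:
            continue
        ok = True
        for sid in by_role.get(Role.CASE, []):
            g = v.genotypes[sid]
            if g is GenotypeCall.MISSING:
                ok = ok and missing_policy == "lenient"
            else:
                ok = ok and g is GenotypeCall.HOM_ALT
        for sid in by_role.get(Role.OBLIGATE_CARRIER, []):
            g = v.genotypes[sid]
            if g is GenotypeCall.MISSING:
                ok = ok and missing_policy == "lenient"
            else:
                ok = ok and g is GenotypeCall.HET
        for sid in by_role.get(Role.UNAFFECTED, []):
            g = v.genotypes[sid]
            if g is GenotypeCall.MISSING:
                ok = ok and missing_policy == "lenient"
            else:
                ok = ok and g is not GenotypeCall.HOM_ALT
        if not ok:
            continue
        calls = panel_map.get(v.key, {})
        n_het = sum(1 for c in calls.values() if c is GenotypeCall.HET)
        n_hom = sum(1 for c in calls.values() if c is GenotypeCall.HOM_ALT)
        if n_het <= policy.max_het_carriers and n_hom <= policy.max_hom_alt:
            out.append(v.key)
    return sorted(out)


class TestRunFunnel:
    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        variants, roles, panel_map = _random_cohort(seed)
        policy = PanelPolicy(max_het_carriers=seed % 3, max_hom_alt=seed % 2)
        candidates, report = run_funnel(
            variants, roles, EffectTier(), [panel_map], [policy]
        )
        assert sorted(v.key for v in candidates) == _oracle_survivors(
            variants, roles, panel_map, policy
        )
        counts = report.counts
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("seed", range(10))
    def test_effect_and_segregation_filters_commute(self, seed, quartet_roles):
        variants, _, _ = _random_cohort(seed, n_variants=80)
        tiers = EffectTier()
        a = segregation_filter(
            [v for v in variants if classify_effect(v, tiers) == "HIGH"], quartet_roles
        )
        b = [
            v for v in segregation_filter(variants, quartet_roles)
            if classify_effect(v, tiers) == "HIGH"
        ]
        assert [v.key for v in a] == [v.key for v in b]

    def test_empty_input_all_zero_stages(self, quartet_roles):
        candidates, report = run_funnel([], quartet_roles, EffectTier(), [{}, {}],
                                        [PanelPolicy(), PanelPolicy()])
        assert candidates == []
        assert report.counts == [0, 0, 0, 0, 0]

    def test_two_panel_funnel_has_five_stages(self, quartet_roles):
        # all -> high-effect -> segregating -> panel 1 -> panel 2
        _, report = run_funnel([make_variant("AAHHR")], quartet_roles, EffectTier(),
                               [{}, {}], [PanelPolicy(0, 0), PanelPolicy(1, 0)])
        assert len(report.stages) == 5
        assert [s for s, _ in report.stages] == [
            "all", "high_effect", "segregating", "panel_1", "panel_2",
        ]

    def test_candidates_sorted_by_position(self, quartet_roles):
        vs = [make_variant("AAHHR", pos=p, chrom=c)
              for p, c in [(500, "3"), (100, "3"), (50, "1")]]
        candidates, _ = run_funnel(vs, quartet_roles)
        assert [(v.chrom, v.pos) for v in candidates] == [("1", 50), ("3", 100), ("3", 500)]
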