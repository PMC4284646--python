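"""Dominant-model and breed-contrast filtering: rule enumeration on toy
panels, missing-genotype semantics, monotonicity/idempotence, audit-trail
completeness, and dominance concordance counting."""

import numpy as np
import pytest

from domscan.filters import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ConcordanceResult,
    FilterCriteria,
    Region,
    VariantKey,
    VariantPanel,
    breed_contrast_filter,
    concordance_check,
    dominant_candidate_filter,
)


def panel_from_classes(class_rows, samples=None, groups=None, chrom="23", start=100):
    """Panel from a variants x samples nested list of class codes."""
    arr = np.array(class_rows, dtype=np.int8).T
    n_samples, n_variants = arr.shape
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    variants = [VariantKey(chrom, start + 10 * j, "A", "T") for j in range(n_variants)]
    return VariantPanel(samples, variants, arr, groups)


class TestDominantCandidateFilter:
    def toy_panel(self):
        # samples: sireA, sireB, grandsire, other
        # v0: het in both sires, hom_ref elsewhere  -> the candidate
        # v1: het in sireA only                     -> fails het rule
        # v2: het in both sires but also grandsire  -> fails absence
        # v3: hom_alt in sireA                      -> fails het rule
        # v4: het in both sires, hom_ref elsewhere, but previously seen
        return panel_from_classes(
            [
                [HET, HET, HOM_REF, HOM_REF],
                [HET, HOM_REF, HOM_REF, HOM_REF],
                [HET, HET, HET, HOM_REF],
                [HOM_ALT, HET, HOM_REF, HOM_REF],
                [HET, HET, HOM_REF, HOM_REF],
            ],
            samples=["sireA", "sireB", "grandsire", "other"],
        )

    def criteria(self, **kwargs):
        panel = self.toy_panel()
        defaults = dict(
            required_het=frozenset({"sireA", "sireB"}),
            required_absent=frozenset({"grandsire"}),
            exclude_seen_in={"db": frozenset({panel.variants[4]})},
        )
        defaults.update(kwargs)
        return panel, FilterCriteria(**defaults)

    def test_single_candidate_with_full_audit(self):
        panel, crit = self.criteria()
        kept, audits = dominant_candidate_filter(panel, crit)
        assert kept == [panel.variants[0]]
        removed = [a for a in audits if not a.kept]
        assert len(removed) == 4
        assert all(a.failed_rule for a in removed)
        by_variant = {a.variant: a.failed_rule for a in removed}
        assert by_variant[panel.variants[4]] == "seen_in:db"
        assert by_variant[panel.variants[2]] == "not_absent_in_required_noncarrier"

    def test_previously_seen_excluded_regardless_of_pattern(self):
        panel, crit = self.criteria(
            exclude_seen_in={"db": frozenset({VariantKey("23", 100, "A", "T")})}
        )
        kept, _ = dominant_candidate_filter(panel, crit)
        assert panel.variants[0] not in kept

    def test_consequence_class_restriction(self):
        panel, crit = self.criteria(
            exclude_seen_in={}, consequence_classes=frozenset({"missense"})
        )
        consequences = {panel.variants[0]: "missense", panel.variants[4]: "intronic"}
        kept, _ = dominant_candidate_filter(panel, crit, consequences=consequences)
        assert kept == [panel.variants[0]]

    def test_missing_in_carrier_disqualifies(self):
        panel = panel_from_classes(
            [[MISSING, HET, HOM_REF, HOM_REF]],
            samples=["sireA", "sireB", "grandsire", "other"],
        )
        crit = FilterCriteria(required_het=frozenset({"sireA", "sireB"}))
        kept, audits = dominant_candidate_filter(panel, crit)
        assert kept == [] and audits[0].failed_rule == "not_het_in_required_carrier"

    def test_missing_in_absent_flags_not_removes(self):
        panel = panel_from_classes(
            [[HET, HET, MISSING, HOM_REF]],
            samples=["sireA", "sireB", "grandsire", "other"],
        )
        crit = FilterCriteria(
            required_het=frozenset({"sireA", "sireB"}),
            required_absent=frozenset({"grandsire"}),
        )
        kept, audits = dominant_candidate_filter(panel, crit)
        assert len(kept) == 1
        assert audits[0].flags == ("unconfirmed_absence",)
        strict = FilterCriteria(
            required_het=frozenset({"sireA", "sireB"}),
            required_absent=frozenset({"grandsire"}),
            strict_absence=True,
        )
        kept_strict, _ = dominant_candidate_filter(panel, strict)
        assert kept_strict == []

    def test_idempotent_and_monotone(self):
        panel, crit = self.criteria()
        kept1, _ = dominant_candidate_filter(panel, crit)
        sub = VariantPanel(
            panel.samples,
            kept1,
            panel.classes[:, [panel.variants.index(k) for k in kept1]],
        )
        kept2, _ = dominant_candidate_filter(sub, crit)
        assert kept2 == kept1
        # enlarging required_absent can only shrink the candidate set
        panel2, bigger = self.criteria(
            required_absent=frozenset({"grandsire", "other"})
        )
        kept3, _ = dominant_candidate_filter(panel2, bigger)
        assert set(kept3) <= set(kept1)

    def test_empty_panel_empty_result(self):
        panel = VariantPanel(["a"], [], np.empty((1, 0), dtype=np.int8))
        kept, audits = dominant_candidate_filter(
            panel, FilterCriteria(required_het=frozenset({"a"}))
        )
        assert kept == [] and audits == []

    def test_empty_required_het_rejected(self):
        panel = self.toy_panel()
        with pytest.raises(ValueError):
            dominant_candidate_filter(panel, FilterCriteria(required_het=frozenset()))


class TestBreedContrastFilter:
    def test_planted_variant_kept(self):
        n_in, n_out = 9, 20
        col = [HET] * n_in + [HOM_REF] * n_out
        panel = panel_from_classes([col], chrom="20")
        kept, _ = breed_contrast_filter(
            panel, panel.samples[:n_in], panel.samples[n_in:]
        )
        assert kept == panel.variants

    def test_missing_in_in_group_drops(self):
        col = [MISSING] + [HET] * 8 + [HOM_REF] * 20
        panel = panel_from_classes([col], chrom="20")
        kept, audits = breed_contrast_filter(
            panel, panel.samples[:9], panel.samples[9:]
        )
        assert kept == [] and audits[0].failed_rule == "not_carried_by_all_in_group"

    def test_pooled_in_group_missing_from_one_breed_empty(self):
        # variant carried by "breed1" (first 9) but not the pooled additions
        col = [HET] * 9 + [HOM_REF] * 6 + [HOM_REF] * 15
        panel = panel_from_classes([col], chrom="20")
        pooled_in = panel.samples[:15]  # breed1 + breed2
        kept, _ = breed_contrast_filter(panel, pooled_in, panel.samples[15:])
        assert kept == []

    def test_region_restriction(self):
        col = [HET] * 3 + [HOM_REF] * 3
        panel = panel_from_classes([col], chrom="20", start=100)
        kept, audits = breed_contrast_filter(
            panel, panel.samples[:3], panel.samples[3:],
            region=Region("20", 1000, 2000),
        )
        assert kept == [] and audits[0].failed_rule == "outside_region"

    def test_overlapping_groups_rejected(self):
        panel = panel_from_classes([[HET, HET, HOM_REF]])
        with pytest.raises(ValueError, match="overlap"):
            breed_contrast_filter(panel, ["s1", "s2"], ["s2", "s3"])

    def test_out_group_growth_is_monotone(self):
        rng = np.random.default_rng(12)
        classes = rng.integers(0, 3, size=(30, 8), endpoint=False).astype(np.int8)
        panel = VariantPanel(
            [f"s{i}" for i in range(30)],
            [VariantKey("1", 100 + j, "A", "G") for j in range(8)],
            classes,
        )
        in_g = panel.samples[:5]
        kept_small, _ = breed_contrast_filter(panel, in_g, panel.samples[5:15])
        kept_big, _ = breed_contrast_filter(panel, in_g, panel.samples[5:30])
        assert set(kept_big) <= set(kept_small)


class TestConcordance:
    def test_fully_concordant_large_cohort(self):
        classes = {f"aff{i}": HET for i in range(1045)}
        classes.update({f"un{i}": HOM_REF for i in range(1160)})
        phen = {s: s.startswith("aff") for s in classes}
        res = concordance_check(classes, phen)
        assert (res.n_concordant, res.n_discordant) == (2205, 0)

    def test_slick_cohort_79_of_82(self):
        classes = {}
        phen = {}
        for i in range(41):  # slick carriers
            classes[f"cc{i}"] = HET
            phen[f"cc{i}"] = True
        classes["case_noncarrier"] = HOM_REF
        phen["case_noncarrier"] = True
        for i in range(2):  # nonslick carriers
            classes[f"dc{i}"] = HET
            phen[f"dc{i}"] = False
        for i in range(38):
            classes[f"ctrl{i}"] = HOM_REF
            phen[f"ctrl{i}"] = False
        res = concordance_check(classes, phen)
        assert (res.n_concordant, res.n_discordant) == (79, 3)
        assert set(res.discordant_ids) == {"case_noncarrier", "dc0", "dc1"}

    def test_empty_phenotype_vacuous(self):
        res = concordance_check({"a": HET}, {})
        assert (res.n_concordant, res.n_discordant, res.discordant_ids) == (0, 0, ())

    def test_missing_genotypes_counted_separately(self):
        res = concordance_check({"a": MISSING, "b": HET}, {"a": True, "b": True})
        assert res.n_missing_genotype == 1 and res.n_concordant == 1
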