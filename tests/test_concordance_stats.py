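"""Mutation matching, fractional allocation and aggregate concordance."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from ctdna_concord.concordance_stats import (
    FractionalCounts,
    MutationMatch,
    PairCategory,
    aggregate_concordance,
    allocate_fractions,
    classify_pair,
    concordance_from_pairs,
    distinct_mutation_summary,
    match_mutations,
    mutation_spectrum,
    pairs_from_listing,
    proportion_ci,
)
from ctdna_concord.core_io import SamplePair, SampleType
from conftest import make_call, make_callset


def build_match(n_concordant=0, n_tdna=0, n_ctdna=0):
    mk = lambda tag, i: ("chr1", 1000 * (i + 1), "C", tag)
    return MutationMatch(
        concordant=frozenset(mk("A", i) for i in range(n_concordant)),
        tdna_only=frozenset(
            mk("T", i + n_concordant) for i in range(n_tdna)
        ),
        ctdna_only=frozenset(
            mk("G", i + n_concordant + n_tdna) for i in range(n_ctdna)
        ),
    )


def brute_force_allocation(match):
    """Oracle: give every mutation weight 1/T and sum weights per group."""
    t = match.total
    if t == 0:
        return FractionalCounts(tn=Fraction(1))
    w = Fraction(1, t)
    tp = fp = fn = Fraction(0)
    for _ in match.concordant:
        tp += w
    for _ in match.ctdna_only:
        fp += w
    for _ in match.tdna_only:
        fn += w
    return FractionalCounts(tp=tp, fp=fp, fn=fn)


class TestMatching:
    def test_identical_variant_both_sides(self):
        t = make_call(sample_type=SampleType.TUMOR, depth=2000, alt_reads=600)
        p = make_call(depth=12_000, alt_reads=120)
        match = match_mutations([t], [p])
        assert len(match.concordant) == 1
        assert not match.tdna_only and not match.ctdna_only

    def test_discordant_counts(self):
        tumor = [make_call(pos=i, sample_type=SampleType.TUMOR,
                           depth=2000, alt_reads=600) for i in (1, 2)]
        plasma = [make_call(pos=i, depth=12_000, alt_reads=120)
                  for i in (10, 11, 12)]
        match = match_mutations(tumor, plasma)
        assert (len(match.concordant), len(match.tdna_only),
                len(match.ctdna_only)) == (0, 2, 3)

    def test_both_empty(self):
        match = match_mutations([], [])
        assert match.total == 0

    def test_vaf_irrelevant_to_matching(self):
        t = make_call(sample_type=SampleType.TUMOR, depth=2000, alt_reads=1200)
        p = make_call(depth=12_000, alt_reads=13)  # very different VAF
        assert len(match_mutations([t], [p]).concordant) == 1

    def test_duplicate_keys_collapse_with_warning(self):
        dup = [make_call(depth=12_000, alt_reads=120),
               make_call(depth=12_000, alt_reads=125)]
        with pytest.warns(UserWarning, match="duplicate"):
            match = match_mutations([], dup)
        assert len(match.ctdna_only) == 1


class TestClassification:
    @pytest.mark.parametrize(
        "c,t,p,expected",
        [
            (0, 0, 0, PairCategory.NONE),
            (1, 0, 0, PairCategory.CONCORDANT_ONLY),
            (1, 0, 1, PairCategory.CONCORDANT_PLUS_DISCORDANT),
            (1, 1, 0, PairCategory.CONCORDANT_PLUS_DISCORDANT),
            (0, 2, 0, PairCategory.TDNA_ONLY),
            (0, 0, 3, PairCategory.CTDNA_ONLY),
            (0, 2, 3, PairCategory.DISCORDANT_BOTH),
        ],
    )
    def test_categories(self, c, t, p, expected):
        assert classify_pair(build_match(c, t, p)) is expected


class TestAllocation:
    def test_worked_example_three_fp_two_fn(self):
        """3 plasma-only + 2 tumor-only: weight 1/5 = 0.20 each, so
        0.6 FP and 0.4 FN pair-equivalents, exactly."""
        frac = allocate_fractions(build_match(0, 2, 3))
        assert frac.fp == Fraction(3, 5)
        assert frac.fn == Fraction(2, 5)
        assert frac.tp == frac.tn == 0
        assert float(frac.fp) == 0.6 and float(frac.fn) == 0.4

    def test_mutation_free_pair_is_one_true_negative(self):
        assert allocate_fractions(build_match()) == FractionalCounts(
            tn=Fraction(1)
        )

    def test_pure_pairs(self):
        assert allocate_fractions(build_match(2, 0, 0)).tp == 1
        assert allocate_fractions(build_match(0, 3, 0)).fn == 1
        assert allocate_fractions(build_match(0, 0, 4)).fp == 1

    def test_mixed_pair_with_concordant(self):
        frac = allocate_fractions(build_match(2, 0, 1))
        assert frac.tp == Fraction(2, 3)
        assert frac.fp == Fraction(1, 3)
        assert frac.fn == 0

    def test_equals_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(500):
            match = build_match(*rng.integers(0, 6, size=3))
            assert allocate_fractions(match) == brute_force_allocation(match)

    def test_conservation_is_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(500):
            frac = allocate_fractions(build_match(*rng.integers(0, 8, size=3)))
            assert frac.total == 1


class TestAggregation:
    def test_two_clean_pairs(self):
        counts = [
            FractionalCounts(tp=Fraction(1)),
            FractionalCounts(tn=Fraction(1)),
        ]
        s = aggregate_concordance(counts)
        assert s.concordance_rate == s.sensitivity == s.specificity == s.ppv == 1.0

    def test_single_fully_discordant_pair(self):
        s = aggregate_concordance([allocate_fractions(build_match(0, 2, 3))])
        assert s.concordance_rate == 0.0
        assert s.sensitivity == 0.0
        assert s.specificity == 0.0
        assert s.ppv == 0.0

    def test_mutation_free_cohort_has_undefined_sensitivity_and_ppv(self):
        counts = [FractionalCounts(tn=Fraction(1))] * 3
        s = aggregate_concordance(counts)
        assert s.sensitivity is None and s.sensitivity_ci is None
        assert s.ppv is None
        assert s.specificity == 1.0 and s.concordance_rate == 1.0

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            aggregate_concordance([])

    def test_cohort_conservation(self, default_cohort):
        pairs, _, _ = default_cohort
        summary, per_pair = concordance_from_pairs(pairs)
        assert float(summary.totals.total) == pytest.approx(len(pairs))
        assert per_pair[["tp", "fp", "fn", "tn"]].sum(axis=1).tolist() == (
            pytest.approx([1.0] * len(pairs))
        )

    def test_perfect_concordance_limit(self):
        """Plasma identical to tumor gives concordance 1 regardless of
        mutation counts."""
        pairs = []
        rng = np.random.default_rng(5)
        for i in range(6):
            n_mut = int(rng.integers(0, 5))
            tumor = [
                make_call(pos=100 + j, sample_type=SampleType.TUMOR,
                          depth=2000, alt_reads=600, sample_id=f"P{i}-T")
                for j in range(n_mut)
            ]
            plasma = [
                make_call(pos=100 + j, depth=12_000, alt_reads=120,
                          sample_id=f"P{i}-P")
                for j in range(n_mut)
            ]
            pairs.append(
                SamplePair(
                    patient_id=f"P{i}",
                    tumor=make_callset(tumor, SampleType.TUMOR, 2000, f"P{i}-T"),
                    plasma=make_callset(plasma, SampleType.PLASMA, 12_000, f"P{i}-P"),
                    wbc=make_callset([], SampleType.WBC, 2000, f"P{i}-W"),
                )
            )
        summary, _ = concordance_from_pairs(pairs)
        assert summary.concordance_rate == 1.0

    def test_category_allocation_coherence(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            match = build_match(*rng.integers(0, 4, size=3))
            frac = allocate_fractions(match)
            cat = classify_pair(match)
            assert (cat is PairCategory.NONE) == (frac.tn == 1)
            assert (cat is PairCategory.CONCORDANT_ONLY) == (frac.tp == 1)


class TestProportionCi:
    def test_zero_numerator_lower_bound_is_zero(self):
        lo, _ = proportion_ci(0, 20)
        assert lo == 0.0

    def test_full_numerator_upper_bound_is_one(self):
        _, hi = proportion_ci(20, 20)
        assert hi == 1.0

    def test_wilson_closed_form_value(self):
        # Wilson for 14/26 evaluated independently:
        # p=7/13, z=1.959964; center/half from the closed form
        n, z, p = 26, 1.959964, 14 / 26
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = proportion_ci(14, 26, "wilson")
        assert (lo, hi) == pytest.approx((center - half, center + half), abs=1e-6)
        assert (lo, hi) == pytest.approx((0.354, 0.712), abs=2e-3)

    def test_wilson_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in ((14, 26), (3, 58), (45, 58)):
            want = proportion_confint(k, n, method="wilson")
            assert proportion_ci(k, n, "wilson") == pytest.approx(want, abs=1e-9)

    def test_fractional_counts_accepted(self):
        lo, hi = proportion_ci(14.9, 25.9)
        assert 0 < lo < 14.9 / 25.9 < hi < 1

    def test_clopper_pearson_brackets_wilson(self):
        w = proportion_ci(14, 26, "wilson")
        cp = proportion_ci(14, 26, "clopper-pearson")
        assert cp[0] <= w[0] and cp[1] >= w[1]

    def test_zero_denominator_undefined(self):
        assert proportion_ci(0, 0) is None


class TestSpectrum:
    def test_distinct_mutation_reconciliation(self):
        """59 tDNA + 76 ctDNA - 34 concordant = 101 distinct over 45
        positive pairs = 2.24 mutations per positive pair."""
        out = distinct_mutation_summary(59, 76, 34, 45)
        assert out["distinct_mutations"] == 101
        assert out["grand_total_double_counted"] == 135
        assert out["mean_per_positive_pair"] == pytest.approx(2.24, abs=0.005)

    def test_single_gene_rate(self):
        t1 = make_call(sample_type=SampleType.TUMOR, depth=2000,
                       alt_reads=600, gene="EGFR", sample_id="P1-T")
        pairs = [
            SamplePair(
                "P1",
                make_callset([t1], SampleType.TUMOR, 2000, "P1-T"),
                make_callset([], SampleType.PLASMA, 12_000, "P1-P"),
                make_callset([], SampleType.WBC, 2000, "P1-W"),
            ),
            SamplePair(
                "P2",
                make_callset([], SampleType.TUMOR, 2000, "P2-T"),
                make_callset([], SampleType.PLASMA, 12_000, "P2-P"),
                make_callset([], SampleType.WBC, 2000, "P2-W"),
            ),
        ]
        spec = mutation_spectrum(pairs)
        assert spec["gene_sample_rates"]["tumor"]["EGFR"] == 0.5
        assert spec["class_proportions"]["tumor"] == {"SNP": 1.0}
        assert spec["n_positive_pairs"] == 1

    def test_empty_cohort_spectrum(self):
        assert mutation_spectrum([])["gene_sample_rates"] == {
            "tumor": {}, "plasma": {},
        }


class TestListingEncoder:
    def test_round_trip_through_listing(self):
        listing = pd.DataFrame(
            [
                ("P1", "both", "chr7", 100, "C", "T"),
                ("P1", "plasma", "chr7", 200, "G", "A"),
                ("P2", "tumor", "chr12", 300, "A", "G"),
                ("P2", "tumor", "chr12", 400, "A", "G"),
                ("P2", "plasma", "chr12", 500, "C", "A"),
                ("P2", "plasma", "chr12", 600, "C", "A"),
                ("P2", "plasma", "chr12", 700, "C", "A"),
                ("P3", "", "", 0, "", ""),  # mutation-free pair
            ],
            columns=["patient_id", "compartment", "chrom", "pos", "ref", "alt"],
        )
        matches = pairs_from_listing(listing)
        assert len(matches) == 3
        cats = [classify_pair(m) for m in matches]
        assert cats == [
            PairCategory.CONCORDANT_PLUS_DISCORDANT,
            PairCategory.DISCORDANT_BOTH,
            PairCategory.NONE,
        ]
        frac = allocate_fractions(matches[1])
        assert float(frac.fp) == 0.6 and float(frac.fn) == 0.4
        s = aggregate_concordance([allocate_fractions(m) for m in matches])
        assert float(s.totals.total) == 3.0

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            pairs_from_listing(pd.DataFrame({"patient_id": ["P1"]}))
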