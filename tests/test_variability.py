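import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sporevar.errors import ValidationError
from sporevar.gene_sets import GeneSet
from sporevar.simulate import SyntheticConfig, simulate_coverage
from sporevar.variability import (
    CATEGORIES,
    ThresholdConfig,
    VariabilityRecord,
    classify_gene,
    classify_universe,
    compute_cv,
    compute_range,
    derive_range_threshold,
    evaluate_replicate,
    implied_fraction,
    median_gene_reads,
)

from conftest import make_bundle


class TestCvAndRange:
    def test_constant_profile_has_zero_cv_and_range(self):
        assert compute_cv([7, 7, 7, 7]) == 0.0
        assert compute_range([7, 7, 7]) == 0.0

    def test_cv_hand_computed_with_sample_sd(self):
        # sd([1..5], n-1) = sqrt(2.5) = 1.58114; mean = 3
        assert compute_cv([1, 2, 3, 4, 5]) == pytest.approx(
            math.sqrt(2.5) / 3, abs=1e-12
        )
        assert round(compute_cv([1, 2, 3, 4, 5]), 4) == 0.5270

    def test_cv_scale_invariance(self):
        base = np.array([1, 2, 3, 4, 5], float)
        assert compute_cv(10 * base) == pytest.approx(compute_cv(base), rel=1e-12)

    def test_range_direct(self):
        assert compute_range([1, 2, 3, 4, 5]) == 4.0
        assert compute_range([0, 5000, 100]) == 5000.0

    def test_all_zero_profile_cv_is_zero(self):
        assert compute_cv(np.zeros(10)) == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10**6), factor=st.floats(0.01, 1000.0))
    def test_scale_properties_on_random_profiles(self, seed, factor):
        counts = np.random.default_rng(seed).gamma(2.0, 100.0, size=50)
        assert compute_cv(counts * factor) == pytest.approx(
            compute_cv(counts), rel=1e-9
        )
        assert compute_range(counts * factor) == pytest.approx(
            factor * compute_range(counts), rel=1e-9
        )


class TestEvaluateReplicate:
    def make_profile(self, counts, adjusted=False):
        return make_bundle(
            counts_by_sample={"WT_r1": counts}, length=len(counts), adjusted=adjusted
        ).profile("WT", 1)

    @pytest.mark.parametrize(
        "counts, expect_meets",
        [
            # CV arm only: CV ~0.53 >= 0.11, range 4 < 2000
            ([1, 2, 3, 4, 5], True),
            # range arm only: CV of a near-constant high profile, range >= 2000
            ([100000] * 50 + [102500], True),
            # neither arm
            ([1000, 1001, 1002, 1001, 1000], False),
        ],
    )
    def test_or_rule(self, counts, expect_meets):
        rec = evaluate_replicate(self.make_profile(counts))
        assert rec.meets is expect_meets

    def test_thresholds_inclusive_at_boundary(self):
        cfg = ThresholdConfig(cv_min=0.11, range_min=2000.0)
        assert cfg.meets(0.11, 0.0) and cfg.meets(0.0, 2000.0)
        assert not cfg.meets(0.1099, 1999.9)

    def test_adjusted_profile_rejected_when_strict(self):
        prof = self.make_profile([1, 2, 3], adjusted=True)
        with pytest.raises(ValidationError, match="unadjusted"):
            evaluate_replicate(prof)
        with pytest.warns(UserWarning):
            evaluate_replicate(prof, strict=False)


def records_from_flags(flags, gene="g"):
    """Six records with forced meets flags: WT r1-3 then MUT r1-3."""
    out = []
    for i, meets in enumerate(flags):
        strain, rep = ("WT", i + 1) if i < 3 else ("MUT", i - 2)
        cv = 1.0 if meets else 0.0  # cv arm carries the flag
        out.append(VariabilityRecord(gene, strain, rep, cv, 0.0, bool(meets)))
    return out


def caption_oracle(flags):
    """Literal restatement of the five color rules over the six flags."""
    wt, mut = flags[:3], flags[3:]
    if all(wt) and all(mut):
        return "common"
    if all(wt):
        return "wt_only"
    if all(mut):
        return "mutant_only"
    if not any(flags):
        return "below_threshold"
    return "partial"


class TestClassifyGene:
    def test_matches_caption_oracle_on_all_64_flag_combinations(self):
        for flags in itertools.product([False, True], repeat=6):
            assert classify_gene(records_from_flags(flags)) == caption_oracle(flags)

    @pytest.mark.parametrize(
        "flags, expected",
        [
            ((1, 1, 1, 0, 0, 0), "wt_only"),
            ((1, 1, 0, 0, 0, 0), "partial"),
            ((0, 0, 0, 0, 0, 0), "below_threshold"),
            ((1, 1, 1, 1, 1, 1), "common"),
            ((0, 0, 0, 1, 1, 1), "mutant_only"),
        ],
    )
    def test_rule_table_examples(self, flags, expected):
        assert classify_gene(records_from_flags(flags)) == expected

    def test_within_strain_replicate_relabeling_invariance(self):
        for flags in itertools.product([False, True], repeat=6):
            recs = records_from_flags(flags)
            for wt_perm in itertools.permutations(recs[:3]):
                relabeled = [
                    VariabilityRecord(r.gene_id, r.strain, i + 1, r.cv, r.range, r.meets)
                    for i, r in enumerate(wt_perm)
                ] + recs[3:]
                assert classify_gene(relabeled) == classify_gene(recs)

    def test_wrong_multiplicity_rejected(self):
        with pytest.raises(ValidationError):
            classify_gene(records_from_flags((1, 1, 1, 0, 0, 0))[:5])


class TestClassifyUniverse:
    def test_counts_partition_simulated_universe(self):
        cfg = SyntheticConfig(seed=11, n_genes=40, gene_length_range=(300, 600))
        bundles, truth = simulate_coverage(cfg)
        universe = GeneSet.from_iterable(truth["gene_id"])
        res = classify_universe(bundles, universe)
        counts = res.summary["category_counts"]
        assert sum(counts.values()) == len(universe)
        assert set(counts) == set(CATEGORIES)
        assert res.summary["exclusive_total"] == counts["wt_only"] + counts["mutant_only"]

    def test_all_constant_profiles_below_threshold(self):
        bundles = {g: make_bundle(g, length=20) for g in ("a", "b")}
        res = classify_universe(bundles, GeneSet.from_iterable(["a", "b"]))
        assert res.summary["category_counts"]["below_threshold"] == 2

    def test_empty_universe_gives_empty_outputs(self):
        res = classify_universe({}, GeneSet.from_iterable([]))
        assert len(res.records) == 0 and len(res.categories) == 0
        assert sum(res.summary["category_counts"].values()) == 0

    def test_missing_bundle_listed(self):
        with pytest.raises(ValidationError, match="ghost"):
            classify_universe(
                {"a": make_bundle("a")}, GeneSet.from_iterable(["a", "ghost"])
            )

    def test_scatter_dots_share_gene_color(self):
        cfg = SyntheticConfig(seed=11, n_genes=6, gene_length_range=(300, 400))
        bundles, truth = simulate_coverage(cfg)
        res = classify_universe(bundles, GeneSet.from_iterable(truth["gene_id"]))
        scatter = res.scatter_table()
        assert (scatter.groupby("gene_id")["color"].nunique() == 1).all()
        assert len(scatter) == 6 * len(truth)


class TestRangeThresholdDerivation:
    def test_fraction_identity(self):
        bundles = {"a": make_bundle("a", {"WT_r1": [100] * 10}, length=10)}
        rep = derive_range_threshold(bundles, fraction=1.0)
        assert rep["range_threshold"] == rep["median_reads"]

    def test_single_constant_gene_median(self):
        bundles = {
            "a": make_bundle("a", {s: [42.0] * 10 for s in
                                   ("WT_r1", "WT_r2", "WT_r3",
                                    "MUT_r1", "MUT_r2", "MUT_r3")}, length=10)
        }
        assert median_gene_reads(bundles) == 42.0

    def test_implied_fraction_matches_reported_arithmetic(self):
        # a 2,000-read range threshold against a median of 5,147 reads
        assert round(100 * implied_fraction(5147, 2000)) == 39

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            median_gene_reads({})
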