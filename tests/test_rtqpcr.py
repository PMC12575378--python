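import numpy as np
import pandas as pd
import pytest

from sporevar.errors import ValidationError
from sporevar.rtqpcr import (
    DEFAULT_AMPLICONS,
    collapse_technical,
    compare_groups,
    ddct,
    efficiencies_comparable,
    primer_efficiency,
)
from sporevar.simulate import simulate_ct


def ct_table(rows):
    return pd.DataFrame(rows, columns=["target", "region", "strain", "bio_rep",
                                       "tech_rep", "ct"])


def simple_table(target_ct_by_strain, ref_ct=15.0, n_bio=3):
    """One target/region; per-strain constant target Ct, shared rnpB Ct."""
    rows = []
    for strain, ct in target_ct_by_strain.items():
        for bio in range(1, n_bio + 1):
            rows.append(("geneA", "A2", strain, bio, 1, ct))
            rows.append(("rnpB", "REF", strain, bio, 1, ref_ct))
    return ct_table(rows)


class TestCollapseTechnical:
    def test_mean_of_technical_replicates(self):
        df = ct_table([
            ("geneA", "A1", "WT", 1, 1, 20.0),
            ("geneA", "A1", "WT", 1, 2, 20.2),
            ("geneA", "A1", "WT", 1, 3, 19.8),
        ])
        out = collapse_technical(df)
        assert len(out) == 1 and out["ct"].iloc[0] == pytest.approx(20.0)

    def test_groups_collapsed_independently(self):
        df = ct_table([
            ("geneA", "A1", "WT", 1, 1, 20.0),
            ("geneA", "A1", "WT", 2, 1, 24.0),
            ("geneA", "A2", "WT", 1, 1, 30.0),
        ])
        out = collapse_technical(df)
        assert len(out) == 3


class TestDdct:
    def test_reference_strain_fold_is_one(self):
        out = ddct(simple_table({"WT": 20.0, "MUT": 22.0}))
        wt = out[out["strain"] == "WT"]
        assert np.allclose(wt["fold"], 1.0)
        assert wt["delta_delta_ct"].mean() == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mut_ct, fold", [(22.0, 0.25), (18.0, 4.0)])
    def test_two_cycle_shifts_give_exact_folds(self, mut_ct, fold):
        out = ddct(simple_table({"WT": 20.0, "MUT": mut_ct}))
        mut = out[out["strain"] == "MUT"]
        assert np.allclose(mut["fold"], fold)

    def test_plate_offset_invariance(self):
        base = simple_table({"WT": 20.0, "MUT": 22.5})
        shifted = base.assign(ct=base["ct"] + 3.7)
        pd.testing.assert_frame_equal(
            ddct(base)[["fold"]], ddct(shifted)[["fold"]]
        )

    def test_missing_reference_row_named(self):
        df = simple_table({"WT": 20.0, "MUT": 22.0})
        df = df[~((df["region"] == "REF") & (df["strain"] == "MUT")
                  & (df["bio_rep"] == 2))]
        with pytest.raises(ValidationError, match="bio_rep=2"):
            ddct(df)

    def test_noise_free_simulation_closed_loop(self):
        truth = {
            ("geneA", "A1", "WT"): 1.0,
            ("geneA", "A1", "MUT"): 1.0,
            ("geneA", "A2", "WT"): 1.0,
            ("geneA", "A2", "MUT"): 0.25,
        }
        out = ddct(simulate_ct(truth, noise_sd=0.0, seed=1))
        means = out.groupby(["target", "region", "strain"])["fold"].mean()
        for (gene, region, strain), fold in truth.items():
            assert means[(gene, region, strain)] == pytest.approx(fold, abs=1e-12)

    def test_noisy_recovery_and_significance(self):
        """Fold 0.25 at the 3' amplicon recovers within 0.1 and flags
        WT-vs-MUT significance in >= 90% of seeded runs."""
        truth = {("geneA", "A2", s): f for s, f in [("WT", 1.0), ("MUT", 0.25)]}
        ok_fold = ok_sig = 0
        n_runs = 30
        for seed in range(n_runs):
            out = ddct(simulate_ct(truth, noise_sd=0.15, seed=seed))
            mut_mean = out.loc[out["strain"] == "MUT", "fold"].mean()
            ok_fold += abs(mut_mean - 0.25) <= 0.1
            tests = compare_groups(out, value="fold")
            ok_sig += bool(tests["significant"].iloc[0])
        assert ok_fold >= 0.9 * n_runs
        assert ok_sig >= 0.9 * n_runs


class TestPrimerEfficiency:
    def test_perfect_doubling_slope(self):
        # slope -3.3219 per log10 dilution <=> one doubling per cycle
        curve = [(d, 30.0 - 3.3219 * d) for d in (0.0, 1.0, 2.0, 3.0)]
        eff = primer_efficiency(np.array(curve))
        assert round(100 * eff.efficiency, 1) == 100.0
        assert eff.valid and eff.r_squared == pytest.approx(1.0)

    def test_closed_form_at_slope_minus_3_6(self):
        curve = [(d, 30.0 - 3.6 * d) for d in (0.0, 1.0, 2.0)]
        eff = primer_efficiency(np.array(curve))
        assert eff.efficiency == pytest.approx(10 ** (1 / 3.6) - 1, abs=1e-9)

    def test_two_points_rejected(self):
        with pytest.raises(ValidationError):
            primer_efficiency(np.array([(0.0, 30.0), (1.0, 27.0)]))

    def test_positive_slope_flagged_invalid(self):
        curve = [(d, 20.0 + 2.0 * d) for d in (0.0, 1.0, 2.0)]
        assert not primer_efficiency(np.array(curve)).valid

    def test_similarity_tolerance(self):
        a = primer_efficiency(np.array([(d, 30 - 3.3219 * d) for d in range(4)]), "t")
        b = primer_efficiency(np.array([(d, 28 - 3.6 * d) for d in range(4)]), "ref")
        assert abs(a.efficiency - b.efficiency) > 0.10
        assert not efficiencies_comparable(a, b)
        assert efficiencies_comparable(a, a)


class TestCompareGroups:
    def expr(self, folds_by_strain):
        rows = []
        for strain, folds in folds_by_strain.items():
            for i, f in enumerate(folds, 1):
                rows.append({"target": "g", "region": "A2", "strain": strain,
                             "bio_rep": i, "fold": f,
                             "delta_delta_ct": -np.log2(f)})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        out = compare_groups(self.expr({"WT": [1, 1, 1], "MUT": [1, 1, 1]}))
        assert not out["significant"].any()
        assert out["degenerate"].all()

    def test_separated_groups_with_jitter_flagged(self):
        jitter = [0.0, 0.01, -0.01]
        out = compare_groups(self.expr({
            "WT": [1 + j for j in jitter], "MUT": [2 + j for j in jitter],
        }))
        assert out["significant"].all()

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups(self.expr({"WT": [1, 1.1, 0.9]}))


def test_amplicon_map_intervals_ordered():
    for gene in ("asnO", "cotT"):
        a1 = DEFAULT_AMPLICONS[(gene, "A1")]
        a2 = DEFAULT_AMPLICONS[(gene, "A2")]
        assert a1[0] < a1[1] and a2[0] < a2[1]
        assert a1[1] < a2[0]  # 5' amplicon strictly upstream of 3' amplicon
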