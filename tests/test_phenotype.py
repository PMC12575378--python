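import numpy as np
import pandas as pd
import pytest

from sporevar.errors import ValidationError
from sporevar.phenotype import (
    germination_table,
    morphometry_compare,
    normalize_germination,
    sporulation_efficiency,
)
from sporevar.simulate import simulate_cfu, simulate_morphometry


def cfu_table(rows):
    return pd.DataFrame(rows, columns=["strain", "bio_rep", "cfu_total", "cfu_heat"])


class TestSporulationEfficiency:
    def test_percentages_by_hand(self):
        out = sporulation_efficiency(cfu_table([
            ("WT", 1, 1e8, 5e7),
            ("WT", 2, 1.1e8, 3.4e7),
            ("MUT", 1, 1e8, 0.0),
            ("MUT", 2, 1e8, 1e7),
        ]))
        eff = out["per_replicate"]["efficiency_pct"].tolist()
        assert eff[0] == pytest.approx(50.0)
        assert eff[1] == pytest.approx(30.9090909, abs=1e-4)
        assert eff[2] == 0.0

    def test_heat_exceeding_total_flagged_but_kept(self):
        out = sporulation_efficiency(cfu_table([
            ("WT", 1, 1e6, 1.1e6), ("WT", 2, 1e6, 9e5),
            ("MUT", 1, 1e6, 3e5), ("MUT", 2, 1e6, 2e5),
        ]))
        rep = out["per_replicate"]
        assert rep["heat_exceeds_total"].iloc[0]
        assert len(rep) == 4
        assert rep["efficiency_pct"].iloc[0] > 100

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            sporulation_efficiency(cfu_table([("WT", 1, 0.0, 0.0)]))

    def test_simulated_binomial_recovery_within_3_se(self):
        eff_true = 0.45
        df = simulate_cfu({"WT": eff_true}, total_cfu=1e6, n_reps=6,
                          rep_sd=0.0, seed=9)
        out = sporulation_efficiency(df)
        strain = out["per_strain"].iloc[0]
        se = strain["std"] / np.sqrt(strain["n"])
        assert abs(strain["mean"] - 100 * eff_true) <= 3 * se


class TestGermination:
    def test_normalisation_by_initial_od(self):
        out = normalize_germination([0, 30, 60], [0.5, 0.4, 0.35])
        np.testing.assert_allclose(out, [1.0, 0.8, 0.7])

    def test_first_ratio_exactly_one_and_outgrowth_rise(self):
        out = normalize_germination([0, 30], [0.5, 0.55])
        assert out[0] == 1.0 and out[1] == pytest.approx(1.1)

    def test_constant_od_all_ones(self):
        np.testing.assert_array_equal(
            normalize_germination([0, 10, 20], [0.4] * 3), [1.0] * 3
        )

    def test_zero_initial_od_rejected(self):
        with pytest.raises(ValidationError):
            normalize_germination([0, 10], [0.0, 0.1])

    def test_long_format_table(self):
        df = pd.DataFrame({
            "strain": ["WT"] * 3 + ["MUT"] * 3,
            "bio_rep": [1] * 6,
            "time_min": [0, 15, 30] * 2,
            "od": [0.5, 0.4, 0.35, 0.6, 0.5, 0.45],
        })
        out = germination_table(df)
        assert (out.groupby("strain")["od_ratio"].first() == 1.0).all()


def morph_table(radii_by_strain, cortex_by_strain):
    rows = []
    for strain in radii_by_strain:
        for i, (r, c) in enumerate(
            zip(radii_by_strain[strain], cortex_by_strain[strain]), 1
        ):
            rows.append({"spore_id": f"{strain}{i}", "strain": strain,
                         "radius_nm": r, "cortex_nm": c})
    return pd.DataFrame(rows)


class TestMorphometry:
    def test_identical_groups_null(self):
        df = morph_table({"WT": [300, 310, 320], "MUT": [300, 310, 320]},
                         {"WT": [90, 91, 92], "MUT": [90, 91, 92]})
        out = morphometry_compare(df)
        assert not out["significant"].any()
        assert out.set_index("metric").loc["radius_nm", "median_MUT"] == 310

    def test_median_order_statistic_and_permutation_invariance(self):
        df = morph_table({"WT": [320, 300, 310], "MUT": [280, 290, 285]},
                         {"WT": [90, 91, 92], "MUT": [60, 61, 62]})
        out = morphometry_compare(df).set_index("metric")
        assert out.loc["radius_nm", "median_WT"] == 310
        shuffled = df.sample(frac=1, random_state=0).reset_index(drop=True)
        out2 = morphometry_compare(shuffled).set_index("metric")
        assert out.loc["radius_nm", "median_WT"] == out2.loc["radius_nm", "median_WT"]

    def test_ratio_recomputed_not_trusted(self):
        df = morph_table({"WT": [300, 300], "MUT": [300, 300]},
                         {"WT": [100, 100], "MUT": [50, 50]})
        df["ratio"] = 999.0  # stale column must be ignored
        out = morphometry_compare(df).set_index("metric")
        assert out.loc["ratio", "median_WT"] == pytest.approx(3.0)
        assert out.loc["ratio", "median_MUT"] == pytest.approx(6.0)

    def test_cortex_fitting_inside_spore_enforced(self):
        df = morph_table({"WT": [100, 100], "MUT": [100, 100]},
                         {"WT": [250, 90], "MUT": [60, 61]})
        with pytest.raises(ValidationError, match="cortex"):
            morphometry_compare(df)

    def test_singleton_group_rejected(self):
        df = morph_table({"WT": [300], "MUT": [300, 310]},
                         {"WT": [90], "MUT": [60, 61]})
        with pytest.raises(ValidationError):
            morphometry_compare(df)

    def test_generated_separation_detected(self):
        """Cortex means 91 vs 61 nm (sd 10, n=30) must flag at alpha 0.01."""
        df = simulate_morphometry(n=30, seed=4)
        out = morphometry_compare(df, alpha=0.01).set_index("metric")
        assert out.loc["cortex_nm", "significant"]
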