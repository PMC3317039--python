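import numpy as np
import pandas as pd
import pytest

import subfrac as sf
from subfrac.stats import average_runs


@pytest.fixture(scope="module")
def u_cohort():
    return sf.sample_cohort_counts(sf.DoseModel(), 4, 13, seed=42)


class TestMixedAnova:
    def test_matches_pingouin_on_dose_by_side_design(self, u_cohort):
        """Independent oracle: the stratum decomposition must reproduce the
        published mixed-ANOVA F statistics for the one-within case."""
        pingouin = pytest.importorskip("pingouin")
        table = sf.mixed_anova(u_cohort, "total_count")
        cells = (u_cohort.groupby(["subject_id", "dose_um", "side"],
                                  observed=True)["total_count"]
                 .mean().reset_index())
        oracle = pingouin.mixed_anova(data=cells, dv="total_count",
                                      within="side", subject="subject_id",
                                      between="dose_um")
        for mine, theirs in (("dose_um", "dose_um"), ("side", "side"),
                             ("dose_um:side", "Interaction")):
            got = float(table.loc[table["factor"] == mine, "F"].iloc[0])
            want = float(oracle.loc[oracle["Source"] == theirs, "F"].iloc[0])
            assert got == pytest.approx(want, rel=1e-9)

    def test_reports_all_design_factors(self, u_cohort):
        table = sf.mixed_anova(u_cohort, "synaptic_count")
        assert set(table["factor"]) == {"dose_um", "side", "dose_um:side",
                                        "distance_um", "dose_um:distance_um"}
        assert (table["p"].between(0, 1)).all()

    def test_degrees_of_freedom_for_balanced_design(self, u_cohort):
        table = sf.mixed_anova(u_cohort, "total_count").set_index("factor")
        assert table.loc["dose_um", "df"] == 2
        assert table.loc["dose_um", "df_error"] == 9  # 12 subjects - 3 doses
        assert table.loc["side", "df_error"] == 9
        assert table.loc["distance_um", "df"] == 12
        assert table.loc["distance_um", "df_error"] == 108  # 9 * 12

    def test_constant_outcome_reports_p_of_one(self, u_cohort):
        df = u_cohort.copy()
        df["flat"] = 5.0
        table = sf.mixed_anova(df, "flat")
        assert (table["p"] == 1.0).all()

    def test_single_dose_level_rejected(self, u_cohort):
        df = u_cohort[u_cohort["dose_um"] == 0.1]
        with pytest.raises(sf.ValidationError):
            sf.mixed_anova(df, "total_count")

    def test_subject_missing_one_side_rejected(self, u_cohort):
        df = u_cohort[~((u_cohort["subject_id"] == "s001")
                        & (u_cohort["side"] == "injected"))]
        with pytest.raises(sf.ValidationError):
            sf.mixed_anova(df, "total_count")

    def test_missing_cells_warn(self, u_cohort):
        df = u_cohort[~((u_cohort["subject_id"] == "s001")
                        & (u_cohort["distance_um"] == 0.0))]
        with pytest.warns(UserWarning, match="unbalanced"):
            sf.mixed_anova(df, "total_count")


class TestTukey:
    def test_two_levels_rejected(self, u_cohort):
        df = u_cohort[u_cohort["dose_um"].isin([0.01, 1.0])]
        with pytest.raises(sf.ValidationError):
            sf.tukey_posthoc(df, "total_count")

    def test_all_pairs_reported(self, u_cohort):
        table = sf.tukey_posthoc(u_cohort, "total_count")
        assert len(table) == 3  # 3 choose 2 dose pairs
        assert (table["p_adj"].between(0, 1)).all()

    def test_u_shape_contrasts_significant_with_strong_effects(self, u_cohort):
        table = sf.tukey_posthoc(u_cohort, "total_count").set_index("pair")
        pairs = {(a, b): p for a, b, p in zip(table["level_a"],
                                              table["level_b"],
                                              table["p_adj"])}
        def p_of(a, b):
            return pairs.get((a, b), pairs.get((b, a)))
        assert p_of("1.0", "0.1") < 0.05
        assert p_of("0.01", "0.1") < 0.05


class TestAncova:
    def test_slope_recovery(self):
        """synaptic = 0.5·total + dose effect + noise → slope ≈ 0.5."""
        rng = np.random.default_rng(0)
        slopes = []
        for rep in range(30):
            rows = []
            for i, dose in enumerate([0.01, 0.1, 1.0] * 20):  # 60 subjects
                sid = f"s{i:03d}"
                for side in ("injected", "contralateral"):
                    total = rng.normal(100, 10)
                    synaptic = (0.5 * total + 5 * np.log10(dose / 0.01 + 1)
                                + rng.normal(0, 1))
                    rows.append({"subject_id": sid, "dose_um": dose,
                                 "side": side, "total": total,
                                 "synaptic": synaptic})
            res = sf.ancova(pd.DataFrame(rows), "synaptic", "total")
            slopes.append(res["slope"])
        assert abs(np.mean(slopes) - 0.5) < 0.025  # |bias| < 5 % of slope

    def test_dose_effect_detected_and_adjusted(self, u_cohort):
        res = sf.ancova(u_cohort, "synaptic_count", "total_count")
        assert res["dose_p"] < 0.05
        assert "dose_um" in res["table"].index

    def test_constant_covariate_rejected(self, u_cohort):
        df = u_cohort.copy()
        df["const"] = 7.0
        with pytest.raises(sf.ValidationError):
            sf.ancova(df, "synaptic_count", "const")

    def test_interaction_term_optional(self, u_cohort):
        res = sf.ancova(u_cohort, "synaptic_count", "total_count",
                        include_interaction=True)
        assert "dose_um:side" in res["table"].index


class TestBlotHelpers:
    def test_normalize_blot_arithmetic(self):
        assert sf.normalize_blot(10.0, 5.0) == pytest.approx(2.0)
        # scale invariance
        assert sf.normalize_blot(30.0, 15.0) == pytest.approx(
            sf.normalize_blot(10.0, 5.0))
        with pytest.raises(sf.ValidationError):
            sf.normalize_blot(10.0, 0.0)

    def test_ratios_averaged_across_replicate_runs(self):
        runs = [[2.0, 3.0, 4.0], [4.0, 5.0, 6.0]]
        assert np.allclose(average_runs(runs), [3.0, 4.0, 5.0])

    def test_blot_measurement_ratio(self):
        lane = sf.BlotMeasurement("L1", "TNFa", 12.0, 4.0)
        assert lane.normalized_ratio == pytest.approx(3.0)
        with pytest.raises(sf.ValidationError):
            sf.BlotMeasurement("L2", "albumin", 0.0, 4.0)

    def test_linear_range_r2(self):
        loadings = np.array([1.0, 2.0, 3.0, 4.0])
        assert sf.linear_range_r2(loadings, 2 * loadings + 1) == pytest.approx(1.0)
        doubled = np.tile(loadings, 2)
        assert sf.linear_range_r2(
            doubled, 2 * doubled + 1) == pytest.approx(1.0)
        with pytest.raises(sf.ValidationError):
            sf.linear_range_r2([1, 2], [1, 2])

    def test_uninformative_intensities_give_near_zero_r2(self):
        rng = np.random.default_rng(1)
        r2s = [sf.linear_range_r2(np.arange(200),
                                  rng.normal(10, 1, size=200))
               for _ in range(20)]
        assert np.mean(r2s) < 0.05

    def test_band_background_correction(self):
        flat = np.full(50, 7.0)
        assert sf.band_background_correct(flat, (20, 30)) == pytest.approx(0.0)
        profile = np.full(50, 7.0)
        profile[20:30] += 3.0  # band of height s=3, width 10
        assert sf.band_background_correct(profile, (20, 30)) == pytest.approx(30.0)
        assert sf.band_background_correct(2 * profile, (20, 30)) == pytest.approx(60.0)
        with pytest.raises(sf.ValidationError):
            sf.band_background_correct(profile, (0, 10))
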