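import json
import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import dopakin as dk
from dopakin.errors import (
    ConfigurationError,
    DomainError,
    IncompleteDesignError,
    InsufficientDataError,
    SingularDesignError,
)
from dopakin.rtm import _interaction_f_cellmeans


def make_design(d1, d2, base1=None, base2=None):
    """Two-arm cohort table from change scores (baselines default to 1..n)."""
    d1, d2 = np.asarray(d1, float), np.asarray(d2, float)
    b1 = np.arange(1.0, d1.size + 1) if base1 is None else np.asarray(base1, float)
    b2 = np.arange(1.0, d2.size + 1) if base2 is None else np.asarray(base2, float)
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(d1.size + d2.size)],
            "arm": [dk.ARM_TEST_RETEST] * d1.size + [dk.ARM_CHALLENGE] * d2.size,
            "ki_scan1": np.concatenate([b1, b2]),
            "ki_scan2": np.concatenate([b1 + d1, b2 + d2]),
        }
    )


class TestLevene:
    def test_identical_groups_null(self):
        w, p = dk.levene([(0.0, 1.0, 2.0), (0.0, 1.0, 2.0)])
        assert w == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_sums_of_squares_example(self):
        # |dev| groups (1,0,1) and (2,0,2): between/within ratio gives W = 0.8
        w, _ = dk.levene([(0, 1, 2), (0, 2, 4)], center="mean")
        assert w == pytest.approx(0.8, abs=1e-12)

    def test_scaling_one_group_increases_w(self):
        rng = np.random.default_rng(0)
        g1, g2 = rng.normal(size=20), rng.normal(size=20)
        w_base, _ = dk.levene([g1, g2])
        w_scaled, _ = dk.levene([g1, 10.0 * g2])
        assert w_scaled > w_base

    def test_median_center_is_brown_forsythe(self):
        rng = np.random.default_rng(1)
        g1, g2 = rng.normal(size=15), rng.exponential(size=15)
        w_ours, p_ours = dk.levene([g1, g2], center="median")
        w_scipy, p_scipy = sps.levene(g1, g2, center="median")
        assert w_ours == pytest.approx(w_scipy)

    def test_guards(self):
        with pytest.raises(InsufficientDataError):
            dk.levene([(1.0, 2.0)])
        with pytest.raises(InsufficientDataError):
            dk.levene([(1.0, 2.0), (3.0,)])
        with pytest.raises(DomainError):
            dk.levene([(1, 2), (3, 4)], center="mode")


class TestMixedAnovaInteraction:
    def test_null_interaction_when_change_distributions_match(self):
        d = np.array([0.1, -0.2, 0.05, 0.3])
        res = dk.mixed_anova_interaction(make_design(d, d))
        assert res.f == pytest.approx(0.0, abs=1e-20)

    def test_derived_example_f6_df_1_4(self):
        # changes (0,1,2) vs (2,3,4): two-sample t = -2.449, F = t^2 = 6
        cohort = make_design([0, 1, 2], [2, 3, 4],
                             base1=[1, 2, 3], base2=[0, 0, 0])
        res = dk.mixed_anova_interaction(cohort)
        assert res.f == pytest.approx(6.0, abs=1e-10)
        assert (res.df1, res.df2) == (1, 4)

    def test_equals_squared_change_score_t_on_random_designs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n1, n2 = rng.integers(3, 12, size=2)
            d1, d2 = rng.normal(size=n1), rng.normal(size=n2)
            res = dk.mixed_anova_interaction(make_design(d1, d2))
            t, df = sps.ttest_ind(d1, d2, equal_var=True), n1 + n2 - 2
            assert res.f == pytest.approx(float(t.statistic) ** 2, abs=1e-10)
            assert res.df2 == df
            assert res.p == pytest.approx(float(t.pvalue), abs=1e-10)

    def test_matches_pingouin_mixed_anova(self):
        cohort = dk.generate_cohort(dk.CohortConfig(seed=5))
        res = dk.mixed_anova_interaction(cohort)
        long = cohort.melt(id_vars=["subject_id", "arm"],
                           value_vars=["ki_scan1", "ki_scan2"],
                           var_name="scan", value_name="ki")
        aov = pg.mixed_anova(long, dv="ki", within="scan", subject="subject_id",
                             between="arm")
        f_pg = float(aov.loc[aov["Source"] == "Interaction", "F"].iloc[0])
        assert res.f == pytest.approx(f_pg, rel=1e-6)

    def test_cellmeans_sums_of_squares_path_agrees(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            cohort = make_design(rng.normal(size=6), rng.normal(size=9))
            assert _interaction_f_cellmeans(cohort) == pytest.approx(
                dk.mixed_anova_interaction(cohort).f, abs=1e-10
            )

    def test_incomplete_design_rejected(self):
        df = make_design([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(IncompleteDesignError):
            dk.mixed_anova_interaction(df[df["arm"] == dk.ARM_CHALLENGE])
        df2 = df.copy()
        df2.loc[0, "ki_scan2"] = np.nan
        with pytest.raises(IncompleteDesignError):
            dk.mixed_anova_interaction(df2)


class TestInteractionRegression:
    def test_exact_identity_two_arms(self):
        rng = np.random.default_rng(9)
        b1, b2 = rng.normal(10, 1, 6), rng.normal(10, 1, 8)
        cohort = make_design(np.zeros(6), np.zeros(8), base1=b1, base2=b2)
        fit = dk.interaction_regression(cohort)
        assert fit.coefficients["baseline"] == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients["intercept"] == pytest.approx(0.0, abs=1e-8)
        assert fit.coefficients["baseline_x_group"] == pytest.approx(0.0, abs=1e-8)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("gamma", [0.0, 0.25, 0.6, 1.0])
    def test_recovers_minus_gamma_on_noise_free_cohorts(self, gamma):
        cohort = dk.generate_cohort(
            dk.CohortConfig(gamma=gamma, sigma_measure=0.0, sigma_drift=0.0, seed=11)
        )
        fit = dk.interaction_regression(cohort)
        assert fit.coefficients["baseline_x_group"] == pytest.approx(-gamma, abs=1e-8)

    def test_pure_noise_outcome_has_near_zero_adjusted_r2(self):
        rng = np.random.default_rng(12)
        n = 2500
        cohort = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(2 * n)],
                "arm": [dk.ARM_TEST_RETEST] * n + [dk.ARM_CHALLENGE] * n,
                "ki_scan1": rng.normal(0.014, 0.0015, 2 * n),
                "ki_scan2": rng.normal(0.014, 0.0015, 2 * n),  # independent of scan1
            }
        )
        fit = dk.interaction_regression(cohort)
        assert abs(fit.adjusted_r2) < 0.02

    def test_single_arm_is_rank_deficient(self):
        df = make_design([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        single = df.copy()
        single["arm"] = dk.ARM_TEST_RETEST
        with pytest.raises(SingularDesignError):
            dk.interaction_regression(single)

    def test_small_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            dk.interaction_regression(make_design([0.1], [0.2, 0.3]))


class TestFisherZ:
    @pytest.mark.parametrize("r, z", [(0.0, 0.0), (0.5, 0.5493061443)])
    def test_values(self, r, z):
        assert dk.fisher_z(r) == pytest.approx(z, abs=1e-9)

    @given(z=st.floats(-5.0, 5.0))
    @settings(deadline=None, max_examples=100)
    def test_roundtrip_through_tanh(self, z):
        assert dk.fisher_z(math.tanh(z)) == pytest.approx(z, abs=1e-12, rel=1e-9)

    @given(r=st.floats(-0.999, 0.999))
    @settings(deadline=None, max_examples=50)
    def test_odd_function(self, r):
        assert dk.fisher_z(-r) == pytest.approx(-dk.fisher_z(r), abs=1e-12)

    def test_domain(self):
        with pytest.raises(DomainError):
            dk.fisher_z(1.0)


class TestCompareCorrelations:
    def test_equal_correlations_null(self):
        res = dk.compare_correlations(0.4, 10, 0.4, 20)
        assert res.z_diff == 0.0 and res.p_two_tailed == pytest.approx(1.0)

    def test_printed_study_pair_does_not_reach_significance(self):
        # r = -0.57 (n=8) vs r = -0.90 (n=11): hand Fisher-z arithmetic gives
        # |z| ~ 1.45, p ~ 0.15 under the independent-samples comparison
        res = dk.compare_correlations(-0.57, 8, -0.90, 11)
        assert abs(res.z_diff) == pytest.approx(1.4466, abs=2e-3)
        assert res.p_two_tailed == pytest.approx(0.148, abs=5e-3)
        assert res.p_two_tailed > 0.05

    def test_antisymmetry(self):
        a = dk.compare_correlations(0.3, 15, 0.7, 25)
        b = dk.compare_correlations(0.7, 25, 0.3, 15)
        assert a.z_diff == pytest.approx(-b.z_diff)
        assert a.p_two_tailed == pytest.approx(b.p_two_tailed)

    def test_steiger_dependent_needs_cross_correlation(self):
        with pytest.raises(DomainError):
            dk.compare_correlations(0.3, 20, 0.5, 20, method="steiger_dependent")
        res = dk.compare_correlations(0.3, 20, 0.5, 20, method="steiger_dependent",
                                      r_cross=0.2)
        assert res.method == "steiger_dependent"
        assert 0.0 <= res.p_two_tailed <= 1.0

    def test_guards(self):
        with pytest.raises(InsufficientDataError):
            dk.compare_correlations(0.1, 3, 0.2, 10)
        with pytest.raises(DomainError):
            dk.compare_correlations(1.0, 10, 0.2, 10)


class TestBattery:
    def test_deterministic_null_report(self):
        cfg = dk.CohortConfig(gamma=0.0, sigma_measure=0.0, sigma_drift=0.0, seed=13)
        c = dk.generate_cohort(cfg)
        tr = c[c["arm"] == dk.ARM_TEST_RETEST]
        ch = c[c["arm"] == dk.ARM_CHALLENGE]
        rep = dk.rtm_battery(tr, ch)
        assert rep.anova.f == pytest.approx(0.0, abs=1e-18)
        assert rep.levene_w == 0.0 and rep.levene_p == 1.0
        # zero-variance percent changes cannot be correlated: flagged, not raised
        assert rep.correlation_test_retest is None
        assert "correlation_test_retest" in rep.degenerate

    def test_fields_equal_independent_recomputation(self):
        c = dk.generate_cohort(dk.CohortConfig(gamma=0.6, seed=14))
        tr = c[c["arm"] == dk.ARM_TEST_RETEST]
        ch = c[c["arm"] == dk.ARM_CHALLENGE]
        rep = dk.rtm_battery(tr, ch)
        d_tr = (tr["ki_scan2"] - tr["ki_scan1"]).to_numpy()
        d_ch = (ch["ki_scan2"] - ch["ki_scan1"]).to_numpy()
        # component-wise formula oracle
        t = sps.ttest_ind(d_tr, d_ch, equal_var=True).statistic
        assert rep.anova.f == pytest.approx(t**2, abs=1e-10)
        w, p = sps.levene(d_tr, d_ch, center="mean")
        assert rep.levene_w == pytest.approx(w)
        r_tr = sps.pearsonr(tr["ki_scan1"],
                            (tr["ki_scan1"] - tr["ki_scan2"]) / tr["ki_scan1"]).statistic
        assert rep.correlation_test_retest.r == pytest.approx(r_tr, abs=1e-12)
        z = (np.arctanh(rep.correlation_test_retest.r)
             - np.arctanh(rep.correlation_challenge.r)) / np.sqrt(1 / 5 + 1 / 9)
        assert rep.correlation_comparison.z_diff == pytest.approx(z, abs=1e-12)

    def test_exclusions_change_reported_n(self):
        c = dk.generate_cohort(dk.CohortConfig(gamma=0.6, seed=15))
        tr = c[c["arm"] == dk.ARM_TEST_RETEST]
        ch = c[c["arm"] == dk.ARM_CHALLENGE]
        full = dk.rtm_battery(tr, ch)
        trimmed = dk.rtm_battery(tr, ch, exclusions=("ch001",))
        assert trimmed.correlation_challenge.n == full.correlation_challenge.n - 1
        assert trimmed.excluded_ids == ("ch001",)

    def test_report_roundtrips_through_json(self):
        c = dk.generate_cohort(dk.CohortConfig(gamma=0.6, seed=16))
        rep = dk.rtm_battery(c[c["arm"] == dk.ARM_TEST_RETEST],
                             c[c["arm"] == dk.ARM_CHALLENGE]).to_dict()
        assert json.loads(json.dumps(rep)) == rep
        for block in ("anova", "regression", "correlation_comparison"):
            assert block in rep
        ps = [rep["levene"]["p"], rep["anova"]["p"], rep["regression"]["f_p"],
              rep["correlation_comparison"]["p_two_tailed"]]
        assert all(0.0 <= p <= 1.0 for p in ps)


class TestCalibrationSim:
    def test_small_n_sim_rejected(self):
        with pytest.raises(ConfigurationError):
            dk.calibration_sim([0.0], n_sim=10)
        with pytest.raises(ConfigurationError):
            dk.calibration_sim([0.0], n_sim=200, alpha=1.5)

    def test_output_shape_and_determinism(self):
        a = dk.calibration_sim([0.0, 0.9], n_sim=150, seed=21)
        b = dk.calibration_sim([0.0, 0.9], n_sim=150, seed=21)
        pd.testing.assert_frame_equal(a, b)
        assert list(a["gamma"]) == [0.0, 0.9]
        assert ((a[["anova_rejection_rate", "correlation_rejection_rate"]] >= 0).all().all())

    def test_strong_regulation_detected_by_correlation_comparison(self):
        tab = dk.calibration_sim([0.0, 0.9], n_sim=400, seed=22)
        r0, r9 = tab["correlation_rejection_rate"]
        assert r9 > r0 + 0.2
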