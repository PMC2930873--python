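import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genactiv import (
    SimulationConfig,
    attenuation_percent,
    beta_to_weight,
    build_analysis_table,
    dichotomized_contrast,
    fit_linear,
    fit_logistic,
    interaction_test,
    inverse_normal,
    longitudinal_interaction,
    per_snp_interactions,
    score_main_effect,
    simulate_cohort,
    stratified_effects,
)
from genactiv.errors import DataError, ModelError
from genactiv.models import _outcome_frame, _prepare


def ols_oracle(y, X):
    """Normal-equations estimates and SEs, independent of the fit path."""
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    return beta, se


def logistic_oracle(y, X, n_iter=200):
    """Damped Newton-Raphson logistic MLE, independent implementation."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        step = np.linalg.solve(hess, grad)
        while np.abs(step).max() > 5:
            step /= 2.0
        beta = beta + step
        if np.abs(step).max() < 1e-12:
            break
    return beta


class TestFitLinear:
    def test_noiseless_line(self):
        x = np.arange(10, dtype=float)
        df = pd.DataFrame({"y": 3 + 2 * x, "x": x})
        res = fit_linear("y", ["x"], df)
        assert res.estimate("x") == pytest.approx(2.0, abs=1e-10)
        assert res.se("x") == pytest.approx(0.0, abs=1e-8)

    def test_row_permutation_invariance(self, rng):
        df = pd.DataFrame(
            {"y": rng.normal(size=60), "a": rng.normal(size=60),
             "b": rng.normal(size=60)}
        )
        res1 = fit_linear("y", ["a", "b"], df)
        res2 = fit_linear("y", ["a", "b"], df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(res1.params, res2.params)

    def test_matches_normal_equations_oracle(self, rng):
        n = 50
        df = pd.DataFrame(
            {
                "y": rng.normal(size=n),
                "x1": rng.normal(size=n),
                "x2": rng.normal(size=n),
                "x3": rng.normal(size=n),
            }
        )
        res = fit_linear("y", ["x1", "x2", "x3"], df)
        X = np.column_stack([np.ones(n), df[["x1", "x2", "x3"]].to_numpy()])
        beta, se = ols_oracle(df["y"].to_numpy(), X)
        np.testing.assert_allclose(
            res.params["estimate"].to_numpy(), beta, rtol=1e-8
        )
        np.testing.assert_allclose(res.params["se"].to_numpy(), se, rtol=1e-8)

    def test_rank_deficient_names_terms(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=30), "a": rng.normal(size=30)})
        df["b"] = 2 * df["a"]
        with pytest.raises(ModelError, match="collinear"):
            fit_linear("y", ["a", "b"], df)

    def test_complete_case_drops_missing(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=40), "x": rng.normal(size=40)})
        df.loc[:4, "x"] = np.nan
        res = fit_linear("y", ["x"], df)
        assert res.n_used == 35


class TestFitLogistic:
    def test_two_by_two_table_or(self):
        # exposed 30/70, unexposed 10/90 -> OR = (30*90)/(70*10) = 3.857
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        x = np.r_[np.ones(100), np.zeros(100)]
        df = pd.DataFrame({"y": y, "x": x})
        res = fit_logistic("y", ["x"], df)
        assert float(res.params.loc["x", "or_"]) == pytest.approx(
            30 * 90 / (70 * 10), rel=1e-6
        )

    def test_or_ci_is_exp_of_wald_interval(self):
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        x = np.r_[np.ones(100), np.zeros(100)]
        res = fit_logistic("y", ["x"], pd.DataFrame({"y": y, "x": x}))
        est, se = res.estimate("x"), res.se("x")
        assert float(res.params.loc["x", "or_low"]) == pytest.approx(
            np.exp(est - 1.959963984540054 * se)
        )
        assert float(res.params.loc["x", "or_high"]) == pytest.approx(
            np.exp(est + 1.959963984540054 * se)
        )

    def test_duplication_invariance(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-x))).astype(float)
        df = pd.DataFrame({"y": y, "x": x})
        res1 = fit_logistic("y", ["x"], df)
        res2 = fit_logistic("y", ["x"], pd.concat([df, df], ignore_index=True))
        assert float(res2.params.loc["x", "or_"]) == pytest.approx(
            float(res1.params.loc["x", "or_"]), rel=1e-6
        )

    def test_matches_newton_oracle(self, rng):
        n = 300
        x = rng.normal(size=(n, 2))
        eta = 0.3 + 0.8 * x[:, 0] - 0.5 * x[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        df = pd.DataFrame({"y": y, "a": x[:, 0], "b": x[:, 1]})
        res = fit_logistic("y", ["a", "b"], df)
        X = np.column_stack([np.ones(n), x])
        beta = logistic_oracle(y, X)
        np.testing.assert_allclose(
            res.params["estimate"].to_numpy(), beta, atol=1e-6
        )

    def test_single_class_rejected(self):
        df = pd.DataFrame({"y": np.ones(20), "x": np.arange(20.0)})
        with pytest.raises(ModelError, match="both classes"):
            fit_logistic("y", ["x"], df)

    def test_complete_separation_raises(self):
        x = np.r_[np.linspace(-3, -1, 25), np.linspace(1, 3, 25)]
        y = (x > 0).astype(float)
        with pytest.raises(ModelError):
            fit_logistic("y", ["x"], pd.DataFrame({"y": y, "x": x}))

    def test_null_z_calibration(self):
        """Outcome independent of x: |z| < 3 in at least 99% of 500 seeds."""
        extreme = 0
        n = 400
        for seed in range(500):
            r = np.random.default_rng(seed)
            df = pd.DataFrame(
                {"y": (r.random(n) < 0.3).astype(float), "x": r.normal(size=n)}
            )
            res = fit_logistic("y", ["x"], df)
            z = res.estimate("x") / res.se("x")
            if abs(z) >= 3:
                extreme += 1
        assert extreme <= 5


class TestBetaToWeight:
    @pytest.mark.parametrize(
        "beta, grams",
        [
            (0.154, 445),
            (0.205, 592),
            (0.126, 364),
            (0.131, 379),
            (0.136, 393),
            (0.130, 376),
            (0.739, 2136),
            (0.407, 1176),
        ],
    )
    def test_reference_conversions(self, beta, grams):
        assert beta_to_weight(beta, 1.70) == grams

    def test_zero(self):
        assert beta_to_weight(0.0, 1.80) == 0

    def test_negative_sign_symmetry(self):
        assert beta_to_weight(-0.1, 1.70) == -289
        assert beta_to_weight(-0.154, 1.70) == -beta_to_weight(0.154, 1.70)

    def test_linearity_before_rounding(self):
        # f(a*beta) == a*f(beta) up to rounding
        assert abs(beta_to_weight(0.2, 1.7) - 2 * beta_to_weight(0.1, 1.7)) <= 1

    def test_height_must_be_positive(self):
        with pytest.raises(DataError):
            beta_to_weight(0.1, 0.0)


class TestAttenuationPercent:
    def test_beta_scale_grams(self):
        assert attenuation_percent(592, 379) == 36

    def test_beta_scale_raw_betas(self):
        assert attenuation_percent(0.205, 0.131) == 36

    def test_excess_or_scale(self):
        assert attenuation_percent(1.158, 1.095, scale="excess_or") == 40

    def test_equal_effects(self):
        assert attenuation_percent(0.2, 0.2) == 0

    def test_or_at_most_one_rejected(self):
        with pytest.raises(DataError):
            attenuation_percent(0.99, 0.9, scale="excess_or")

    def test_zero_reference_rejected(self):
        with pytest.raises(DataError):
            attenuation_percent(0.0, 0.1)


class TestInverseNormal:
    def test_middle_of_three_maps_to_zero(self):
        out = inverse_normal([1.0, 5.0, 9.0])
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(
            inverse_normal(x), inverse_normal(np.exp(x)), atol=1e-12
        )

    def test_blom_quantiles_n5(self):
        out = inverse_normal([10.0, 20.0, 30.0, 40.0, 50.0])
        expected = stats.norm.ppf(
            (np.arange(1, 6) - 0.375) / 5.25
        )
        np.testing.assert_allclose(out, expected, atol=1e-12)
        # (r - 3/8)/(n + 1/4) for n=5: 0.1190, 0.3095, 0.5, 0.6905, 0.8810
        np.testing.assert_allclose(
            (np.arange(1, 6) - 0.375) / 5.25,
            [0.11905, 0.30952, 0.5, 0.69048, 0.88095],
            atol=1e-5,
        )

    def test_constant_input_rejected(self):
        with pytest.raises(DataError):
            inverse_normal([2.0, 2.0, 2.0])


class TestScoreMainEffect:
    def test_recovers_generative_effect(self):
        cfg = SimulationConfig(
            n_subjects=8000,
            seed=101,
            beta_per_allele_inactive=0.154,
            interaction_slope=0.0,
        )
        panel, records = simulate_cohort(cfg)
        table, _, _ = build_analysis_table(panel, records)
        res = score_main_effect(table, "bmi")
        assert abs(res.estimate("score") - 0.154) < 3 * res.se("score")

    def test_obesity_set_excludes_overweight_band(self, analysis_table):
        df, col, kind = _outcome_frame(_prepare(analysis_table), "obesity")
        assert kind == "logistic"
        bmi = df["bmi_baseline"]
        assert not ((bmi >= 25) & (bmi < 30)).any()
        assert not (bmi < 18.5).any()

    def test_unknown_outcome(self, analysis_table):
        with pytest.raises(DataError):
            score_main_effect(analysis_table, "waist")


class TestInteractionTest:
    def test_binary_coding_equals_merged_levels(self, analysis_table):
        res_binary = interaction_test(analysis_table, "bmi", coding="binary")
        merged = analysis_table.copy()
        merged["activity"] = (merged["activity"] >= 1).astype(float)
        res_merged = interaction_test(merged, "bmi", coding="ordinal")
        assert res_binary.p_interaction == pytest.approx(
            res_merged.p_interaction, rel=1e-10
        )
        assert res_binary.estimate == pytest.approx(res_merged.estimate, rel=1e-10)

    def test_single_activity_level_rejected(self, analysis_table):
        sub = analysis_table[analysis_table["activity"] == 0]
        with pytest.raises(ModelError, match="single activity level"):
            interaction_test(sub, "bmi")

    def test_detects_generative_interaction(self):
        cfg = SimulationConfig(n_subjects=20_000, seed=71, noise_sd=2.0)
        panel, records = simulate_cohort(cfg)
        table, _, _ = build_analysis_table(panel, records)
        res = interaction_test(table, "bmi", "ordinal")
        assert res.estimate < 0
        assert res.p_interaction < 0.05

    def test_main_effects_present_in_model(self, analysis_table):
        res = interaction_test(analysis_table, "bmi")
        assert {"score", "act_term", "interaction"} <= set(res.model.params.index)


class TestStratifiedEffects:
    def test_strata_labels_and_gram_conversion(self, analysis_table):
        effects = stratified_effects(analysis_table, "bmi")
        labels = [e.stratum for e in effects]
        assert labels[0] == "overall"
        assert "inactive" in labels and "combined_active" in labels
        for e in effects:
            assert e.weight_grams == beta_to_weight(e.beta)

    def test_homogeneous_when_no_interaction(self):
        cfg = SimulationConfig(
            n_subjects=20_000, seed=73, interaction_slope=0.0, noise_sd=2.0
        )
        panel, records = simulate_cohort(cfg)
        table, _, _ = build_analysis_table(panel, records)
        effects = {e.stratum: e for e in stratified_effects(table, "bmi")}
        b_in, b_act = effects["inactive"], effects["active"]
        z = (b_in.beta - b_act.beta) / np.hypot(b_in.se, b_act.se)
        assert abs(z) < 3

    def test_logistic_strata_carry_or(self, analysis_table):
        effects = stratified_effects(analysis_table, "obesity")
        for e in effects:
            assert e.or_per_allele is not None
            assert e.or_ci[0] <= e.or_per_allele <= e.or_ci[1]


class TestDichotomizedContrast:
    def test_median_split_balanced(self, analysis_table):
        effects = dichotomized_contrast(analysis_table, "bmi")
        median = analysis_table["score"].median()
        high = (analysis_table["score"] > median).mean()
        assert 0.3 < high < 0.7  # integer-ish scores: not exactly 50/50
        assert {e.stratum for e in effects} == {"inactive", "combined_active"}

    def test_null_contrast_near_zero(self):
        cfg = SimulationConfig(
            n_subjects=10_000, seed=79, beta_per_allele_inactive=0.0,
            interaction_slope=0.0,
        )
        panel, records = simulate_cohort(cfg)
        table, _, _ = build_analysis_table(panel, records)
        for e in dichotomized_contrast(table, "bmi"):
            assert abs(e.beta) < 3 * e.se

    def test_degenerate_threshold_rejected(self, analysis_table):
        with pytest.raises(DataError, match="degenerate"):
            dichotomized_contrast(analysis_table, "bmi", threshold=1000.0)


class TestPerSnpInteractions:
    def test_bonferroni_arithmetic(self):
        from genactiv.models import bonferroni

        assert bonferroni(0.02, 12) == pytest.approx(0.24)
        assert bonferroni(0.2, 12) == 1.0

    def test_scan_structure(self, small_cohort, analysis_table):
        panel, _ = small_cohort
        sub = panel.subset_subjects(analysis_table["subject_id"])
        scan = per_snp_interactions(
            sub, analysis_table.set_index("subject_id")
        )
        assert len(scan) == 12
        assert (scan["p_bonferroni"] >= scan["p"]).all()
        assert (scan["n_tests"] == 12).all()

    def test_monomorphic_snp_skipped(self, analysis_table):
        from genactiv import GenotypePanel, SnpSpec

        ids = analysis_table["subject_id"].tolist()
        dosage = pd.DataFrame(
            {"rs1": np.ones(len(ids)), "rs2": np.tile([0.0, 1.0, 2.0],
             len(ids))[: len(ids)]},
            index=ids,
        )
        panel = GenotypePanel(
            dosage,
            (SnpSpec("rs1", "A", "G", 0.5), SnpSpec("rs2", "A", "G", 0.5)),
        )
        with pytest.warns(UserWarning, match="monomorphic"):
            scan = per_snp_interactions(
                panel, analysis_table.set_index("subject_id")
            )
        assert bool(scan.loc["rs1", "skipped"])
        assert scan.loc["rs2", "n_tests"] == 1


class TestLongitudinal:
    def test_noiseless_slope_recovery(self):
        cfg = SimulationConfig(
            n_subjects=4000,
            seed=83,
            annual_drift_sd=1e-9,
            drift_score_inactive=0.01,
            drift_score_trend=-0.004,
            dropout_rate=0.0,
            genotype_missing_rate=0.0,
            prevalence_t2d=0.0,
        )
        panel, records = simulate_cohort(cfg)
        # drift depends on the full 12-SNP count: disable the QC drop so a
        # chance HWE failure cannot attenuate the noiseless recovery
        table, _, _ = build_analysis_table(
            panel, records, call_rate_min=0.0, hwe_p_min=0.0
        )
        res, slopes = longitudinal_interaction(table)
        by = {s.stratum: s.beta for s in slopes}
        assert by["inactive"] == pytest.approx(0.01, abs=1e-6)
        assert by["active"] == pytest.approx(0.01 - 3 * 0.004, abs=1e-6)
        assert res.estimate == pytest.approx(-0.004, abs=1e-6)

    def test_null_drift_gives_null_score_term(self):
        cfg = SimulationConfig(
            n_subjects=8000, seed=89,
            drift_score_inactive=0.0, drift_score_trend=0.0,
        )
        panel, records = simulate_cohort(cfg)
        table, _, _ = build_analysis_table(panel, records)
        res, _ = longitudinal_interaction(table)
        m = res.model
        assert abs(m.estimate("score") / m.se("score")) < 3

    def test_sign_pattern_recovered(self):
        cfg = SimulationConfig(
            n_subjects=12_000, seed=97,
            drift_score_inactive=0.02, drift_score_trend=-0.012,
            annual_drift_sd=0.1, dropout_rate=0.2,
        )
        panel, records = simulate_cohort(cfg)
        table, _, _ = build_analysis_table(panel, records)
        res, slopes = longitudinal_interaction(table)
        by = {s.stratum: s.beta for s in slopes}
        assert by["inactive"] > 0
        assert by["active"] < 0
        assert res.p_interaction < 0.05

    def test_no_followup_rejected(self, analysis_table):
        df = analysis_table.copy()
        df["annual_bmi_change"] = np.nan
        with pytest.raises(DataError, match="follow-up"):
            longitudinal_interaction(df)
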