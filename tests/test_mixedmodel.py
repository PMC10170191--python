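import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from dimvision.mixedmodel import (
    EstimateWithCI,
    ModelSpec,
    aic,
    back_transform_estimates,
    fit_lmm,
    likelihood_ratio_test,
    pairwise_comparisons,
    summarize_times,
)


def one_way_data(rng, n_groups=4, n_per=12, sigma_b=0.08, sigma=0.12,
                 level_means=(0.0, 0.0, 0.0, 0.0)):
    """Balanced subjects-by-levels design mirroring the 48-threshold study."""
    subjects = np.repeat([f"b{i}" for i in range(n_groups)], n_per)
    levels = np.tile(np.repeat(["L1", "L2", "L3", "L4"], n_per // 4), n_groups)
    mean = dict(zip(["L1", "L2", "L3", "L4"], level_means))
    b = rng.normal(0, sigma_b, n_groups)
    y = (
        np.array([mean[l] for l in levels])
        + b[np.repeat(np.arange(n_groups), n_per)]
        + rng.normal(0, sigma, n_groups * n_per)
    )
    return pd.DataFrame({"y": y, "subject": subjects, "light_level": levels})


FULL = ModelSpec(response="y", fixed_terms=("light_level",), grouping_factor="subject")
NULL = ModelSpec(response="y", fixed_terms=(), grouping_factor="subject")


class TestFitLMM:
    def test_matches_statsmodels_ml_fit(self, rng):
        """Independent oracle: statsmodels MixedLM with reml=False."""
        df = one_way_data(rng, sigma_b=0.3, level_means=(0.0, 0.5, 0.2, -0.1))
        ours = fit_lmm(df, FULL)
        sm_fit = smf.mixedlm("y ~ C(light_level)", df, groups=df["subject"]).fit(
            reml=False
        )
        assert ours.loglik == pytest.approx(sm_fit.llf, abs=1e-6)
        assert ours.beta.to_numpy() == pytest.approx(sm_fit.fe_params.to_numpy(),
                                                     abs=1e-5)
        assert ours.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)
        assert ours.sigma_b2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]),
                                              rel=1e-2, abs=1e-4)

    def test_zero_group_variance_reduces_to_ols(self, rng):
        """With no between-group structure the ML fit hits the boundary and the
        fixed effects coincide with ordinary least squares."""
        df = one_way_data(rng, sigma_b=0.0, level_means=(1.0, 1.2, 0.9, 1.1))
        fit = fit_lmm(df, FULL)
        X = pd.get_dummies(df["light_level"], drop_first=True).astype(float)
        X.insert(0, "Intercept", 1.0)
        ols_beta, *_ = np.linalg.lstsq(X.to_numpy(), df["y"].to_numpy(), rcond=None)
        if fit.sigma_b2 == 0.0:
            assert fit.beta.to_numpy() == pytest.approx(ols_beta, abs=1e-8)

    def test_boundary_reached_in_majority_of_null_replicates(self):
        hits = 0
        n_rep = 40
        for seed in range(n_rep):
            df = one_way_data(np.random.default_rng(seed), sigma_b=0.0)
            hits += fit_lmm(df, FULL).sigma_b2 == 0.0
        assert hits > n_rep / 2

    def test_deterministic_repeated_fits(self, rng):
        df = one_way_data(rng, sigma_b=0.2)
        a, b = fit_lmm(df, FULL), fit_lmm(df, FULL)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-10)
        assert (a.beta == b.beta).all()

    def test_loglik_not_below_ols_submodel(self, rng):
        df = one_way_data(rng, sigma_b=0.25)
        fit = fit_lmm(df, FULL)
        resid = df["y"] - df.groupby("light_level")["y"].transform("mean")
        s2 = float((resid**2).mean())
        n = len(df)
        ols_ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
        assert fit.loglik >= ols_ll - 1e-8

    def test_parameter_recovery_balanced_design(self):
        """Simulation oracle: bias of the level-mean estimates is small over
        replicates of the 48-observation design."""
        true = np.array([0.0, 0.6, 0.3, -0.2])
        est = np.zeros((200, 4))
        for r in range(200):
            df = one_way_data(np.random.default_rng(10_000 + r),
                              sigma_b=0.1, level_means=tuple(true))
            fit = fit_lmm(df, FULL)
            levels, L = [], None
            ests = back_transform_estimates(fit, "light_level")
            est[r] = [e.point for e in ests]
        bias = est.mean(axis=0) - true
        assert np.all(np.abs(bias) < 0.03)

    def test_single_group_rejected(self, rng):
        df = one_way_data(rng)
        df["subject"] = "b0"
        with pytest.raises(ValueError):
            fit_lmm(df, FULL)

    def test_transform_requires_positive_response(self, rng):
        df = one_way_data(rng)
        spec = ModelSpec(response="y", fixed_terms=("light_level",),
                         grouping_factor="subject", response_transform="log10")
        df.loc[0, "y"] = -1.0
        with pytest.raises(ValueError):
            fit_lmm(df, spec)


class TestLikelihoodRatioTest:
    def test_identical_models_give_zero_statistic(self, rng):
        df = one_way_data(rng, sigma_b=0.1)
        full = fit_lmm(df, FULL)
        # compare against itself through a copy with fewer named params
        reduced = fit_lmm(df, NULL)
        stat, dof, p = likelihood_ratio_test(full, reduced)
        assert stat >= 0.0
        assert dof == 3

    def test_non_nested_rejected(self, rng):
        df = one_way_data(rng)
        df["x"] = rng.normal(size=len(df))
        fit_a = fit_lmm(df, ModelSpec("y", ("light_level",), "subject"))
        fit_b = fit_lmm(df, ModelSpec("y", ("x",), "subject"))
        with pytest.raises(ValueError):
            likelihood_ratio_test(fit_a, fit_b)

    def test_null_rejection_rate_is_calibrated(self):
        """Type-I error at alpha = 0.05 over null simulations of the
        48-threshold design stays near nominal."""
        rng = np.random.default_rng(77)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            df = one_way_data(rng, sigma_b=0.08, sigma=0.12)
            stat, dof, p = likelihood_ratio_test(fit_lmm(df, FULL), fit_lmm(df, NULL))
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09

    def test_statistic_nonnegative_on_many_datasets(self):
        for seed in range(25):
            df = one_way_data(np.random.default_rng(seed), sigma_b=0.05)
            stat, _, _ = likelihood_ratio_test(fit_lmm(df, FULL), fit_lmm(df, NULL))
            assert stat >= 0.0

    def test_bootstrap_statistic_dominated_by_chi2(self):
        """Parametric-bootstrap LRT statistics under the null are stochastically
        below (or near) the chi2_3 reference at the upper tail."""
        from scipy import stats as sps

        rng = np.random.default_rng(5)
        stats_ = []
        for _ in range(300):
            df = one_way_data(rng, sigma_b=0.08, sigma=0.12)
            s, _, _ = likelihood_ratio_test(fit_lmm(df, FULL), fit_lmm(df, NULL))
            stats_.append(s)
        emp_q95 = np.quantile(stats_, 0.95)
        assert emp_q95 <= sps.chi2.ppf(0.95, 3) * 1.25


class TestAIC:
    def test_extra_parameter_costs_two(self, rng):
        df = one_way_data(rng)
        full, null = fit_lmm(df, FULL), fit_lmm(df, NULL)
        delta_params = full.n_params - null.n_params
        assert aic(full) - aic(null) == pytest.approx(
            -2 * (full.loglik - null.loglik) + 2 * delta_params
        )

    def test_row_order_invariance(self, rng):
        df = one_way_data(rng, sigma_b=0.1)
        shuffled = df.sample(frac=1.0, random_state=1)
        assert aic(fit_lmm(df, FULL)) == pytest.approx(
            aic(fit_lmm(shuffled, FULL)), abs=1e-8
        )

    def test_aic_prefers_true_model_under_real_effect(self):
        """At study-sized effects the full model wins on AIC in nearly every
        replicate."""
        true = np.log10([0.825, 0.110, 0.136, 0.106])
        wins = 0
        n_rep = 100
        for r in range(n_rep):
            df = one_way_data(np.random.default_rng(r), sigma_b=0.08, sigma=0.12,
                              level_means=tuple(true))
            wins += aic(fit_lmm(df, FULL)) < aic(fit_lmm(df, NULL))
        assert wins >= 0.95 * n_rep


class TestBackTransform:
    def test_identity_gives_raw_cell_means_when_balanced(self, rng):
        df = one_way_data(rng, sigma_b=0.0, level_means=(1.0, 2.0, 3.0, 4.0))
        fit = fit_lmm(df, FULL)
        ests = {e.label: e.point for e in back_transform_estimates(fit, "light_level")}
        raw = df.groupby("light_level")["y"].mean()
        for label, point in ests.items():
            assert point == pytest.approx(raw[label], abs=1e-6)

    def test_log10_back_transform_arithmetic(self, rng):
        df = one_way_data(rng, sigma_b=0.05, level_means=(-0.96, -0.96, -0.96, -0.96))
        df["y"] = 10.0 ** df["y"]
        spec = ModelSpec("y", ("light_level",), "subject", response_transform="log10")
        fit = fit_lmm(df, spec)
        ests = back_transform_estimates(fit, "light_level")
        for e in ests:
            assert e.point == pytest.approx(0.110, abs=0.03)
            assert e.lower <= e.point <= e.upper

    def test_inverse_transform_swaps_endpoints(self, rng):
        df = one_way_data(rng, sigma_b=0.0, level_means=(1.0, 1.1, 0.9, 1.2))
        df["y"] = np.abs(df["y"]) + 0.5
        spec = ModelSpec("y", ("light_level",), "subject",
                         response_transform="inverse")
        fit = fit_lmm(df, spec)
        for e in back_transform_estimates(fit, "light_level"):
            assert e.lower <= e.point <= e.upper


class TestPairwise:
    def test_identical_levels_give_z_zero(self):
        rng = np.random.default_rng(0)
        df = one_way_data(rng, sigma_b=0.0, sigma=0.1)
        df["y"] = np.where(df["light_level"].isin(["L1", "L2"]), 0.0, 1.0)
        fit = fit_lmm(df, FULL)
        table = pairwise_comparisons(fit, "light_level")
        row = table[table["contrast"] == "L1 - L2"].iloc[0]
        assert row["z"] == pytest.approx(0.0, abs=1e-6)
        assert row["p_adjusted"] == pytest.approx(1.0)

    def test_adjusted_p_monotone(self, rng):
        df = one_way_data(rng, sigma_b=0.1, level_means=(0.0, 0.4, 0.1, -0.3))
        fit = fit_lmm(df, FULL)
        for method in ("holm", "bonferroni"):
            table = pairwise_comparisons(fit, "light_level", adjust=method)
            assert (table["p_adjusted"] >= table["p_unadjusted"] - 1e-15).all()

    def test_power_at_study_effect_size(self):
        """Level-1 mean 0.875 log units above the rest: every level-1 contrast
        significant at 0.001 in nearly all replicates."""
        hits = 0
        n_rep = 100
        for r in range(n_rep):
            df = one_way_data(np.random.default_rng(500 + r), sigma_b=0.08,
                              sigma=0.12, level_means=(0.875, 0.0, 0.0, 0.0))
            table = pairwise_comparisons(fit_lmm(df, FULL), "light_level")
            l1 = table[table["contrast"].str.contains("L1")]
            hits += bool((l1["p_adjusted"] < 0.001).all())
        assert hits >= 0.95 * n_rep


class TestSummarizeTimes:
    def test_constant_times(self):
        from dimvision.staircase import TrialLog, TrialRecord

        records = [
            TrialRecord(session_id="s", subject_id="b", experiment=1, level_id=1,
                        trial_index=i, task="detection", positive_luminance=1.0,
                        negative_luminance=0.0, positive_side="left",
                        chosen_side="left", correct=True, trial_unit="open",
                        response_time=1.5, inter_trial_time=7.0)
            for i in range(1, 6)
        ]
        log = TrialLog("s", "b", 1, 1, "detection", records)
        s = summarize_times([log]).iloc[0]
        assert s["response_time_median"] == s["response_time_q1"] == 1.5
        assert s["inter_trial_median"] == 7.0

    def test_exclusion_applies_to_response_times_only(self, study_logs):
        s = summarize_times(study_logs)
        for _, row in s.iterrows():
            assert row["n_response_time"] < row["n_choices"]

    def test_synthetic_medians_near_configured(self, study_logs):
        s = summarize_times(study_logs).set_index("experiment")
        assert s.loc[1, "response_time_median"] == pytest.approx(1.17, rel=0.1)
        assert s.loc[2, "response_time_median"] == pytest.approx(0.98, rel=0.1)
        assert s.loc[1, "inter_trial_median"] == pytest.approx(8.33, rel=0.1)
        assert s.loc[2, "inter_trial_median"] == pytest.approx(7.79, rel=0.1)
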