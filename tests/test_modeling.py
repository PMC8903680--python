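"""Elastic-net selection, weighted score and logistic inference."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import statsmodels.api as sm

from nmrmet.modeling import (
    _fit_enet_path,
    compute_weighted_score,
    covariate_influence,
    demographics_table,
    endpoint_rows,
    fit_score_logistic,
    hosmer_lemeshow,
    lrt_anova,
    nagelkerke_r2,
    select_signals_enet,
    two_by_two_chi2,
)


def _logistic_data(n, betas, seed, prevalence_intercept=-1.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(betas)))
    eta = prevalence_intercept + X @ np.asarray(betas)
    y = rng.binomial(1, expit(eta)).astype(float)
    Z = pd.DataFrame(X, columns=[f"s{i:02d}" for i in range(len(betas))])
    return Z, pd.Series(y, index=Z.index)


class TestElasticNet:
    def test_huge_lambda_selects_nothing(self):
        Z, y = _logistic_data(200, [1.0, 0.0, 0.0], seed=1)
        fits = _fit_enet_path(Z.to_numpy(), y.to_numpy(), np.array([1e6]), alpha=0.5)
        assert np.all(fits[0].coef_ == 0.0)

    def test_single_class_rejected(self):
        Z, _ = _logistic_data(50, [0.0], seed=2)
        with pytest.raises(ValueError, match="single class"):
            select_signals_enet(Z, np.zeros(50), folds=5)

    def test_strong_signal_always_selected(self):
        for seed in (3, 4, 5):
            Z, y = _logistic_data(400, [3.0] + [0.0] * 9, seed=seed)
            res = select_signals_enet(Z, y, folds=10, seed=seed)
            assert "s00" in res.selected_signal_ids

    def test_tiny_lambda_approaches_unpenalized_fit(self):
        Z, y = _logistic_data(500, [0.8, -0.5], seed=6)
        X = Z.to_numpy()
        fit = sm.Logit(y.to_numpy(), sm.add_constant(X)).fit(disp=0)
        # ridge-only (alpha=0) at vanishing lambda ~ maximum likelihood
        enet = _fit_enet_path(X, y.to_numpy(), np.array([1e-7]), alpha=0.0, tol=1e-8)[0]
        assert np.allclose(enet.coef_[0], fit.params[1:], atol=1e-3)

    def test_lambda_1se_never_selects_more_than_lambda_min(self):
        Z, y = _logistic_data(300, [1.5, 1.0, 0.0, 0.0, 0.0], seed=7)
        rmin = select_signals_enet(Z, y, folds=10, seed=7, lambda_rule="lambda_min")
        r1se = select_signals_enet(Z, y, folds=10, seed=7, lambda_rule="lambda_1se")
        assert r1se.chosen_lambda >= rmin.chosen_lambda
        assert len(r1se.coefficients) <= len(rmin.coefficients)

    def test_subsample_mode_runs_and_is_seeded(self):
        Z, y = _logistic_data(300, [2.0, 0.0], seed=8)
        a = select_signals_enet(Z, y, folds=10, seed=8, cv_mode="subsample")
        b = select_signals_enet(Z, y, folds=10, seed=8, cv_mode="subsample")
        assert a.selected_signal_ids == b.selected_signal_ids
        assert np.allclose(a.cv_deviance, b.cv_deviance)

    def test_matches_r_glmnet_at_fixed_lambda(self, tmp_path):
        """Same objective as glmnet: coefficients agree at a shared lambda
        (standardize=FALSE, alpha=0.5)."""
        Z, y = _logistic_data(300, [1.0, -0.7, 0.0, 0.0], seed=9)
        lam = 0.02
        mine = _fit_enet_path(Z.to_numpy(), y.to_numpy(), np.array([lam]), 0.5, tol=1e-8)[0]
        df = Z.copy()
        df["y"] = y
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = f"""
        suppressMessages(library(glmnet))
        d <- read.csv("{csv}")
        X <- as.matrix(d[, 1:4]); y <- d$y
        f <- glmnet(X, y, family="binomial", alpha=0.5, lambda={lam},
                    standardize=FALSE, thresh=1e-12)
        cat(as.numeric(coef(f)), sep="\\n")
        """
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, check=True
        )
        r_coefs = np.array([float(v) for v in out.stdout.strip().splitlines()])
        assert np.allclose(mine.intercept_[0], r_coefs[0], atol=2e-3)
        assert np.allclose(mine.coef_[0], r_coefs[1:], atol=2e-3)


class TestWeightedScore:
    def test_forced_arithmetic(self):
        from nmrmet.modeling import MetaboliteScore

        score = MetaboliteScore(
            intercept=0.1,
            coefficients=pd.Series({"a": 0.5, "b": -0.2}),
            scores=pd.Series(dtype=float),
        )
        val = score.evaluate(pd.DataFrame({"a": [2.0], "b": [1.0]}))
        assert val.iloc[0] == pytest.approx(0.9)

    def test_refit_recovers_linear_predictor(self):
        Z, y = _logistic_data(800, [1.0, -0.6], seed=10)
        ms = compute_weighted_score(Z, y)
        assert not ms.separation_fallback
        assert np.allclose(ms.scores, ms.evaluate(Z))
        # in-sample refit: regressing y on the score gives slope 1, OR = e
        rep = fit_score_logistic(ms.scores, y, endpoint="x")
        assert rep.odds_ratio == pytest.approx(np.e, rel=1e-6)

    def test_score_beats_every_single_signal(self):
        Z, y = _logistic_data(1200, [0.7, 0.7, 0.7, 0.0], seed=11)
        ms = compute_weighted_score(Z, y)
        def auc(v):
            return stats.mannwhitneyu(v[y == 1], v[y == 0]).statistic / (
                (y == 1).sum() * (y == 0).sum()
            )
        assert auc(ms.scores) > max(auc(Z[c]) for c in Z.columns)

    def test_perfect_separation_falls_back_flagged(self):
        y = pd.Series([0.0] * 20 + [1.0] * 20)
        Z = pd.DataFrame({"s": np.r_[np.zeros(20), np.ones(20)]})
        ms = compute_weighted_score(Z, y)
        assert ms.separation_fallback
        assert np.all(np.isfinite(ms.coefficients))

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            compute_weighted_score(pd.DataFrame(index=[0, 1]), pd.Series([0, 1]))


class TestNagelkerke:
    def test_null_model_gives_zero(self):
        assert nagelkerke_r2(-100.0, -100.0, 50) == 0.0

    def test_perfect_binary_model_gives_one(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        llnull = float(np.sum(np.log(np.where(y == 1, 0.5, 0.5))))
        assert nagelkerke_r2(llnull, 0.0, y.size) == pytest.approx(1.0)

    def test_matches_brute_force_likelihood_grid_on_toy(self):
        """8-row toy: R2 from statsmodels log-likelihoods equals the value
        from an independent brute-force grid maximization."""
        x = np.array([-1.5, -1.0, -0.5, -0.2, 0.2, 0.5, 1.0, 1.5])
        y = np.array([0.0, 0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0])

        def loglik(b0, b1):
            p = expit(b0 + b1 * x)
            return np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

        grid = np.linspace(-4, 4, 801)
        ll_model = max(loglik(b0, b1) for b0 in grid for b1 in grid)
        ll_null = max(loglik(b0, 0.0) for b0 in grid)
        oracle = nagelkerke_r2(ll_null, ll_model, 8)

        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        null = sm.Logit(y, np.ones((8, 1))).fit(disp=0)
        assert nagelkerke_r2(null.llf, fit.llf, 8) == pytest.approx(oracle, abs=1e-4)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            nagelkerke_r2(-10.0, -5.0, 0)


class TestHosmerLemeshow:
    def test_exact_calibration_gives_zero_statistic(self):
        p = np.repeat([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95], 20)
        y = np.concatenate([
            np.r_[np.ones(int(round(20 * q))), np.zeros(20 - int(round(20 * q)))]
            for q in [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95]
        ])
        stat, df, pval = hosmer_lemeshow(p, y, groups=10)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert pval == pytest.approx(1.0)

    def test_ten_groups_gives_eight_df(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0.05, 0.95, 500)
        y = rng.binomial(1, p)
        _, df, _ = hosmer_lemeshow(p, y, groups=10)
        assert df == 8

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([0.5] * 10), np.zeros(10), groups=2)


class TestLRT:
    def test_identical_models_give_zero(self):
        Z, y = _logistic_data(100, [0.5], seed=13)
        X = sm.add_constant(Z.to_numpy())
        fit = sm.Logit(y.to_numpy(), X).fit(disp=0)
        stat, df, p = lrt_anova(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_tail_closed_form(self):
        assert stats.chi2.sf(10.83, 1) == pytest.approx(0.000998, abs=5e-6)

    def test_nested_fit_comparison(self):
        Z, y = _logistic_data(500, [1.0, 0.0], seed=14)
        yv = y.to_numpy()
        full = sm.Logit(yv, sm.add_constant(Z.to_numpy())).fit(disp=0)
        red = sm.Logit(yv, np.ones((500, 1))).fit(disp=0)
        stat, df, p = lrt_anova(full, red)
        assert df == 2
        assert stat == pytest.approx(2 * (full.llf - red.llf))
        assert p < 0.01  # strong true signal

    def test_row_mismatch_rejected(self):
        Z, y = _logistic_data(100, [0.5], seed=15)
        yv = y.to_numpy()
        a = sm.Logit(yv, sm.add_constant(Z.to_numpy())).fit(disp=0)
        b = sm.Logit(yv[:50], np.ones((50, 1))).fit(disp=0)
        with pytest.raises(ValueError):
            lrt_anova(a, b)


class TestScoreLogistic:
    def test_deterministic_outcome_saturates_r2(self):
        score = pd.Series(np.linspace(-3, 3, 500))
        y = (score > 0).astype(float)
        rep = fit_score_logistic(score, y)
        assert rep.r2_unadjusted >= 0.99

    def test_log_or_recovery_within_tolerance(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(30 + seed)
            score = pd.Series(rng.normal(size=1500))
            y = pd.Series(rng.binomial(1, expit(-1.0 + 1.0 * score)).astype(float))
            rep = fit_score_logistic(score, y)
            if abs(np.log(rep.odds_ratio) - 1.0) <= 0.2:
                hits += 1
        assert hits >= 4

    def test_null_score_ci_covers_one(self):
        covered = 0
        reps = 60
        for seed in range(reps):
            rng = np.random.default_rng(60 + seed)
            score = pd.Series(rng.normal(size=600))
            y = pd.Series(rng.binomial(1, 0.3, 600).astype(float))
            rep = fit_score_logistic(score, y)
            if rep.or_ci[0] <= 1.0 <= rep.or_ci[1]:
                covered += 1
        assert stats.binomtest(covered, reps, 0.95).pvalue > 0.01

    def test_adjusted_model_reports_all_statistics(self):
        rng = np.random.default_rng(16)
        n = 800
        cov = pd.DataFrame(
            {
                "age": rng.normal(48, 14, n),
                "sex": rng.binomial(1, 0.5, n),
                "bmi": rng.normal(27, 5, n),
                "smoking": rng.binomial(1, 0.4, n),
            }
        )
        score = pd.Series(rng.normal(size=n) + 0.3 * cov["sex"])
        y = pd.Series(rng.binomial(1, expit(-1.5 + score)).astype(float))
        rep = fit_score_logistic(score, y, cov, endpoint="test")
        assert rep.adjusted_odds_ratio is not None
        assert rep.or_ci[0] < rep.odds_ratio < rep.or_ci[1]
        assert 0.0 <= rep.r2_unadjusted <= rep.r2_full <= 1.0
        stat, df, p = rep.lrt_vs_covariates
        assert df == 1 and stat > 0
        assert rep.n_cases_used + rep.n_controls_used == n


class TestCovariateInfluence:
    def test_injected_effects_flagged_null_effects_covered(self):
        rng = np.random.default_rng(17)
        n = 1200
        cov = pd.DataFrame(
            {
                "age": rng.normal(48, 14, n),
                "sex": rng.binomial(1, 0.5, n),
                "bmi": rng.normal(27, 5, n),
                "smoking": rng.binomial(1, 0.4, n),
            }
        )
        score = pd.Series(
            0.02 * cov["age"] + 0.5 * cov["sex"] + rng.normal(size=n)
        )
        table, strata = covariate_influence(score, cov)
        assert table.loc["age", "p"] < 0.05
        assert table.loc["sex", "p"] < 0.05
        assert table.loc["bmi", "p"] > 0.001  # null covariate, usually clean
        assert {"sex=0", "sex=1"} <= set(strata["stratum"])
        assert (strata.loc[strata.stratum.str.startswith("age"), "n"].sum() == n)

    def test_constant_covariate_flagged(self):
        score = pd.Series(np.random.default_rng(18).normal(size=50))
        cov = pd.DataFrame({"sex": np.ones(50), "age": np.arange(50.0)})
        table, _ = covariate_influence(score, cov)
        assert table.loc["sex", "flag"] == "constant"


class TestDemographics:
    def test_published_smoking_table_reproduces_printed_p(self):
        """Yates-corrected chi-square on the study's smoking counts
        (129/287 cases vs 481/1333 controls) rounds to p = 0.006."""
        chi2, p = two_by_two_chi2(129, 287, 481, 1333)
        assert round(p, 3) == 0.006
        # without continuity correction the rounded value differs
        _, p_raw = two_by_two_chi2(129, 287, 481, 1333, correction=False)
        assert round(p_raw, 3) == 0.005

    def test_identical_groups_give_null_chi2(self):
        chi2, p = two_by_two_chi2(50, 200, 50, 200)
        assert chi2 == 0.0 and p == 1.0

    def test_t_statistic_matches_closed_form_pooled_t(self, templates):
        from nmrmet.simulate import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n_subjects=500, seed=19))
        table = demographics_table(cohort, "lifetime")
        a = cohort.loc[cohort.lifetime == 1, "age"]
        b = cohort.loc[cohort.lifetime == 0, "age"]
        sp = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        t = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        assert table.loc["age", "statistic"] == pytest.approx(t, abs=1e-10)

    def test_endpoint_rows_nesting(self, templates):
        from nmrmet.simulate import CohortConfig, generate_cohort

        cohort = generate_cohort(CohortConfig(n_subjects=400, seed=20)).set_index(
            "subject_id"
        )
        mask_l, y_l = endpoint_rows(cohort, "lifetime")
        mask_a, y_a = endpoint_rows(cohort, "active")
        assert mask_l.all()
        # active endpoint excludes non-active lifetime cases
        excluded = cohort[(cohort.lifetime == 1) & (cohort.active == 0)]
        assert not mask_a.loc[excluded.index].any()
        assert set(y_a.unique()) <= {0, 1}

    def test_empty_group_rejected(self):
        cohort = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "family_id": [0, 1],
                "age": [30.0, 40.0],
                "sex": [0, 1],
                "bmi": [25.0, 26.0],
                "smoking": [0, 1],
                "lifetime": [0, 0],
                "active": [0, 0],
            }
        ).set_index("subject_id")
        with pytest.raises(ValueError):
            demographics_table(cohort, "lifetime")
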