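"""Profile modeling: elastic-net selection and score-based inference.

The discovery step is penalized logistic regression (binomial deviance,
mixing parameter alpha between the L1 and L2 penalties, glmnet's
parameterization) with a seeded, stratified 50-fold cross-validation
over a log-spaced lambda path.  The selected signals are refit without
penalty; the resulting linear predictor is the "weighted metabolite
score", which enters a second logistic model (optionally with age, sex,
BMI and smoking) reported with odds ratios, Nagelkerke R-squared,
Hosmer-Lemeshow calibration and a likelihood-ratio comparison against
the covariates-only model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetResult",
    "MetaboliteScore",
    "InferenceReport",
    "select_signals_enet",
    "compute_weighted_score",
    "fit_score_logistic",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "lrt_anova",
    "covariate_influence",
    "demographics_table",
    "endpoint_rows",
]

COVARIATES = ("age", "sex", "bmi", "smoking")


# ---------------------------------------------------------------- elastic net


@dataclass
class ElasticNetResult:
    alpha: float
    lambda_path: np.ndarray
    cv_deviance: np.ndarray  # mean validation binomial deviance per lambda
    cv_deviance_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    chosen_lambda: float
    coefficients: pd.Series  # nonzero coefficients at chosen lambda
    intercept: float
    n_used: int
    folds: int
    seed: int

    @property
    def selected_signal_ids(self) -> list[str]:
        return list(self.coefficients.index)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _fit_enet_path(
    X: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    alpha: float,
    tol: float = 1e-3,
) -> list[LogisticRegression]:
    """One warm-started saga fit per lambda, largest lambda first.

    Penalized objective matches glmnet's: mean deviance/2 +
    lambda * [alpha*||b||_1 + (1-alpha)/2*||b||^2], via C = 1/(n*lambda).
    """
    n = y.size
    clf = LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        C=1.0,
        warm_start=True,
        fit_intercept=True,
        max_iter=3000,
        tol=tol,
        random_state=0,  # saga samples rows; fixed for bit-determinism
    )
    fits = []
    for lam in lambdas:
        clf.C = 1.0 / (n * lam)
        clf.fit(X, y)
        frozen = LogisticRegression()
        frozen.classes_ = clf.classes_.copy()
        frozen.coef_ = clf.coef_.copy()
        frozen.intercept_ = clf.intercept_.copy()
        fits.append(frozen)
    return fits


def select_signals_enet(
    Z: pd.DataFrame,
    y: pd.Series | np.ndarray,
    alpha: float = 0.5,
    folds: int = 50,
    lambda_rule: str = "lambda_min",
    seed: int = 0,
    n_lambdas: int = 25,
    lambda_min_ratio: float = 2e-3,
    cv_mode: str = "kfold",
) -> ElasticNetResult:
    """Cross-validated elastic-net signal selection for one endpoint.

    Rows with any missing signal are dropped (complete-case selection).
    ``cv_mode='kfold'`` is seeded stratified k-fold CV (k=``folds``);
    ``cv_mode='subsample'`` instead scores ``folds`` random stratified
    90/10 splits.  ``lambda_rule`` is ``lambda_min`` (minimum mean CV
    deviance) or ``lambda_1se``.
    """
    Zc = Z.dropna(axis=0)
    yv = pd.Series(np.asarray(y), index=Z.index).loc[Zc.index].to_numpy(float)
    X = Zc.to_numpy(float)
    n = yv.size
    classes, counts = np.unique(yv, return_counts=True)
    if classes.size < 2:
        raise ValueError("endpoint labels contain a single class")
    if folds > n:
        raise ValueError("more folds than samples")

    # glmnet-style lambda path from the null-model gradient
    lam_max = np.max(np.abs(X.T @ (yv - yv.mean()))) / (n * max(alpha, 1e-3))
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    rs = int(seed) % (2**31 - 1)
    if cv_mode == "kfold":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
    elif cv_mode == "subsample":
        splitter = StratifiedShuffleSplit(
            n_splits=folds, test_size=0.1, random_state=rs
        )
    else:
        raise ValueError(f"unknown cv_mode {cv_mode!r}")

    dev = np.zeros((folds, lambdas.size))
    for f, (tr, va) in enumerate(splitter.split(X, yv)):
        fits = _fit_enet_path(X[tr], yv[tr], lambdas, alpha)
        for j, clf in enumerate(fits):
            p = clf.predict_proba(X[va])[:, 1]
            dev[f, j] = _binomial_deviance(yv[va], p)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)

    j_min = int(np.argmin(mean_dev))
    lam_min = float(lambdas[j_min])
    within = mean_dev <= mean_dev[j_min] + se_dev[j_min]
    lam_1se = float(lambdas[np.flatnonzero(within).min()])
    chosen = lam_min if lambda_rule == "lambda_min" else lam_1se
    if lambda_rule not in ("lambda_min", "lambda_1se"):
        raise ValueError(f"unknown lambda_rule {lambda_rule!r}")

    final = _fit_enet_path(X, yv, lambdas[lambdas >= chosen], alpha)[-1]
    coefs = pd.Series(final.coef_[0], index=Zc.columns)
    nonzero = coefs[np.abs(coefs) > 1e-8]
    return ElasticNetResult(
        alpha=alpha,
        lambda_path=lambdas,
        cv_deviance=mean_dev,
        cv_deviance_se=se_dev,
        lambda_min=lam_min,
        lambda_1se=lam_1se,
        chosen_lambda=float(chosen),
        coefficients=nonzero,
        intercept=float(final.intercept_[0]),
        n_used=n,
        folds=folds,
        seed=seed,
    )


# ------------------------------------------------------------ weighted score


@dataclass
class MetaboliteScore:
    intercept: float
    coefficients: pd.Series
    scores: pd.Series  # per-subject linear predictor
    separation_fallback: bool = False

    def evaluate(self, Z_selected: pd.DataFrame) -> pd.Series:
        return self.intercept + Z_selected @ self.coefficients


def compute_weighted_score(
    Z_selected: pd.DataFrame, y: pd.Series | np.ndarray
) -> MetaboliteScore:
    """Unpenalized logistic refit on the selected signals.

    The per-subject linear predictor (intercept + sum of coefficients
    times standardized signal values) is the weighted metabolite score.
    Complete cases only; perfect separation falls back to a lightly
    ridge-penalized fit and is flagged.
    """
    if Z_selected.shape[1] == 0:
        raise ValueError("selected signal set is empty")
    Zc = Z_selected.dropna(axis=0)
    yv = pd.Series(np.asarray(y), index=Z_selected.index).loc[Zc.index].to_numpy(float)
    X = sm.add_constant(Zc.to_numpy(float))
    fallback = False
    try:
        fit = sm.Logit(yv, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 50):
            raise np.linalg.LinAlgError("unstable fit")
        intercept, coefs = float(fit.params[0]), fit.params[1:]
    except Exception as exc:  # perfect separation or singular Hessian
        logger.warning("logistic refit failed (%s); ridge fallback", exc)
        fallback = True
        clf = LogisticRegression(C=100.0, max_iter=5000)
        clf.fit(Zc.to_numpy(float), yv)
        intercept, coefs = float(clf.intercept_[0]), clf.coef_[0]
    coefficients = pd.Series(np.asarray(coefs), index=Zc.columns)
    scores = pd.Series(
        intercept + Zc.to_numpy(float) @ coefficients.to_numpy(), index=Zc.index
    )
    return MetaboliteScore(
        intercept=intercept,
        coefficients=coefficients,
        scores=scores,
        separation_fallback=fallback,
    )


# ------------------------------------------------------- inference machinery


def nagelkerke_r2(loglik_null: float, loglik_model: float, n: int) -> float:
    """Rescaled likelihood-ratio pseudo R-squared (0..1)."""
    if n <= 0:
        raise ValueError("n must be positive")
    cox_snell = 1.0 - np.exp(2.0 * (loglik_null - loglik_model) / n)
    max_r2 = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(cox_snell / max_r2) if max_r2 > 0 else 0.0


def hosmer_lemeshow(
    fitted_probs: np.ndarray, y: np.ndarray, groups: int = 10
) -> tuple[float, int, float]:
    """Hosmer-Lemeshow goodness-of-fit over deciles of fitted risk.

    Tied probabilities stay in one group (quantile bin edges); a group
    with zero expected variance is merged with its neighbour and the
    degrees of freedom (groups - 2) reduced accordingly.
    """
    if groups < 3:
        raise ValueError("need at least 3 groups")
    p = np.asarray(fitted_probs, float)
    yv = np.asarray(y, float)
    edges = np.unique(np.quantile(p, np.linspace(0, 1, groups + 1)[1:-1]))
    bins = np.searchsorted(edges, p, side="right")

    tab = (
        pd.DataFrame({"bin": bins, "y": yv, "p": p})
        .groupby("bin")
        .agg(n=("y", "size"), obs=("y", "sum"), exp=("p", "sum"), pbar=("p", "mean"))
        .sort_index()
    )
    # merge zero-variance groups into the previous (or next) one
    merged = []
    for _, row in tab.iterrows():
        var = row["n"] * row["pbar"] * (1.0 - row["pbar"])
        if merged and (var == 0 or merged[-1]["_var"] == 0):
            prev = merged[-1]
            for k in ("n", "obs", "exp"):
                prev[k] += row[k]
            prev["pbar"] = prev["exp"] / prev["n"]
            prev["_var"] = prev["n"] * prev["pbar"] * (1 - prev["pbar"])
        else:
            d = row.to_dict()
            d["_var"] = var
            merged.append(d)
    g = len(merged)
    if g < 3:
        # saturated or degenerate fits leave no usable risk groups;
        # calibration is then undefined rather than an error
        logger.warning("Hosmer-Lemeshow: fewer than 3 usable risk groups")
        return float("nan"), max(g - 2, 0), float("nan")
    stat = sum(
        (m["obs"] - m["exp"]) ** 2 / m["_var"] for m in merged if m["_var"] > 0
    )
    df = g - 2
    return float(stat), int(df), float(stats.chi2.sf(stat, df))


def lrt_anova(model_full, model_reduced) -> tuple[float, int, float]:
    """Likelihood-ratio (ANOVA-style) comparison of nested fits.

    Accepts statsmodels results objects fitted on identical rows; the
    statistic is 2*(llf_full - llf_reduced) on the parameter-count
    difference.
    """
    if int(model_full.nobs) != int(model_reduced.nobs):
        raise ValueError("models must be fitted on identical rows")
    df = int(model_full.df_model - model_reduced.df_model)
    if df < 0:
        raise ValueError("models are not nested (full has fewer parameters)")
    stat = max(2.0 * (model_full.llf - model_reduced.llf), 0.0)
    if df == 0:
        return float(stat), 0, 1.0
    return float(stat), df, float(stats.chi2.sf(stat, df))


@dataclass
class InferenceReport:
    endpoint: str
    n_cases_used: int
    n_controls_used: int
    odds_ratio: float
    or_ci: tuple[float, float]
    p_value: float
    r2_unadjusted: float
    adjusted_odds_ratio: float | None = None
    adjusted_or_ci: tuple[float, float] | None = None
    adjusted_p_value: float | None = None
    r2_full: float | None = None
    hosmer_lemeshow: tuple[float, int, float] | None = None
    lrt_vs_covariates: tuple[float, int, float] | None = None
    selected_signals: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "endpoint": self.endpoint,
            "n_cases_used": self.n_cases_used,
            "n_controls_used": self.n_controls_used,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1],
            "p_value": self.p_value,
            "nagelkerke_r2_unadjusted": self.r2_unadjusted,
            "adjusted_odds_ratio": self.adjusted_odds_ratio,
            "adjusted_or_ci_low": self.adjusted_or_ci[0] if self.adjusted_or_ci else None,
            "adjusted_or_ci_high": self.adjusted_or_ci[1] if self.adjusted_or_ci else None,
            "adjusted_p_value": self.adjusted_p_value,
            "nagelkerke_r2_full": self.r2_full,
            "hosmer_lemeshow_stat": self.hosmer_lemeshow[0] if self.hosmer_lemeshow else None,
            "hosmer_lemeshow_df": self.hosmer_lemeshow[1] if self.hosmer_lemeshow else None,
            "hosmer_lemeshow_p": self.hosmer_lemeshow[2] if self.hosmer_lemeshow else None,
            "lrt_stat": self.lrt_vs_covariates[0] if self.lrt_vs_covariates else None,
            "lrt_df": self.lrt_vs_covariates[1] if self.lrt_vs_covariates else None,
            "lrt_p": self.lrt_vs_covariates[2] if self.lrt_vs_covariates else None,
            "selected_signals": list(self.selected_signals),
        }


def _wald(fit, idx: int) -> tuple[float, tuple[float, float], float]:
    b = float(fit.params[idx])
    se = float(fit.bse[idx])
    z = stats.norm.ppf(0.975)
    return (
        float(np.exp(b)),
        (float(np.exp(b - z * se)), float(np.exp(b + z * se))),
        float(2.0 * stats.norm.sf(abs(b / se))) if se > 0 else 0.0,
    )


def fit_score_logistic(
    score: pd.Series,
    y: pd.Series,
    covariates: pd.DataFrame | None = None,
    endpoint: str = "",
) -> InferenceReport:
    """Score-on-status logistic inference, optionally covariate-adjusted.

    Reports the OR per unit score with Wald 95% CI and p, Nagelkerke
    R-squared for the unadjusted and full models, Hosmer-Lemeshow
    calibration of the full model, and the likelihood-ratio test of the
    full model against covariates only.  Complete cases only.
    """
    data = pd.DataFrame({"score": score, "y": y})
    if covariates is not None:
        data = data.join(covariates)
    data = data.dropna()
    yv = data["y"].to_numpy(float)
    n = len(data)

    def _fit(X):
        try:
            return sm.Logit(yv, X).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise ValueError(
                f"logistic fit did not converge (possible separation): {exc}; "
                f"n={n}, cases={int(yv.sum())}, params={X.shape[1]}"
            ) from exc

    X1 = sm.add_constant(data[["score"]].to_numpy())
    fit1 = _fit(X1)
    null = sm.Logit(yv, np.ones((n, 1))).fit(disp=0)
    or1, ci1, p1 = _wald(fit1, 1)
    report = InferenceReport(
        endpoint=endpoint,
        n_cases_used=int(yv.sum()),
        n_controls_used=int(n - yv.sum()),
        odds_ratio=or1,
        or_ci=ci1,
        p_value=p1,
        r2_unadjusted=nagelkerke_r2(null.llf, fit1.llf, n),
    )
    if covariates is None:
        report.hosmer_lemeshow = hosmer_lemeshow(fit1.predict(X1), yv)
        return report

    cov_cols = [c for c in covariates.columns]
    Xf = sm.add_constant(data[["score"] + cov_cols].to_numpy())
    Xr = sm.add_constant(data[cov_cols].to_numpy())
    fitf = _fit(Xf)
    fitr = _fit(Xr)
    orf, cif, pf = _wald(fitf, 1)
    report.adjusted_odds_ratio = orf
    report.adjusted_or_ci = cif
    report.adjusted_p_value = pf
    report.r2_full = nagelkerke_r2(null.llf, fitf.llf, n)
    report.hosmer_lemeshow = hosmer_lemeshow(fitf.predict(Xf), yv)
    report.lrt_vs_covariates = lrt_anova(fitf, fitr)
    return report


# --------------------------------------------------- covariates, demographics


def covariate_influence(
    score: pd.Series, covariates: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Linear models of the score on each covariate, plus strata means.

    Returns (per-covariate slope/SE/p table including a joint fit, and
    a stratified mean-score table: sex, smoking, age tertile, BMI
    tertile) for plotting.
    """
    data = covariates.join(score.rename("score")).dropna()
    rows = {}
    for cov in covariates.columns:
        if data[cov].nunique() < 2:
            rows[cov] = {"slope": np.nan, "se": np.nan, "p": np.nan, "flag": "constant"}
            continue
        X = sm.add_constant(data[[cov]].to_numpy(float))
        fit = sm.OLS(data["score"].to_numpy(), X).fit()
        rows[cov] = {
            "slope": float(fit.params[1]),
            "se": float(fit.bse[1]),
            "p": float(fit.pvalues[1]),
            "flag": "",
        }
    Xj = sm.add_constant(data[list(covariates.columns)].to_numpy(float))
    joint = sm.OLS(data["score"].to_numpy(), Xj).fit()
    rows["joint_F"] = {
        "slope": np.nan,
        "se": np.nan,
        "p": float(joint.f_pvalue),
        "flag": "joint",
    }
    table = pd.DataFrame.from_dict(rows, orient="index")

    strata = []
    for cov in ("sex", "smoking"):
        if cov in data:
            for level, grp in data.groupby(cov):
                strata.append(
                    {"stratum": f"{cov}={level}", "mean_score": grp["score"].mean(),
                     "n": len(grp)}
                )
    for cov in ("age", "bmi"):
        if cov in data:
            tert = pd.qcut(data[cov], 3, labels=["T1", "T2", "T3"], duplicates="drop")
            for level, grp in data.groupby(tert, observed=True):
                strata.append(
                    {"stratum": f"{cov}_{level}", "mean_score": grp["score"].mean(),
                     "n": len(grp)}
                )
    return table, pd.DataFrame(strata)


def demographics_table(cohort: pd.DataFrame, endpoint: str = "lifetime") -> pd.DataFrame:
    """Cases-vs-controls demographics with the conventional tests.

    Continuous variables (age, BMI): mean +- SD per group, pooled
    two-sample t-test.  Binary variables (female sex, smoking): n (%)
    per group, chi-square with Yates continuity correction (2x2).
    Missing values are dropped per variable and counted.
    """
    rows_mask, y = endpoint_rows(cohort, endpoint)
    sub = cohort.loc[rows_mask]
    cases = sub[y == 1]
    controls = sub[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("empty case or control group")

    out = {}
    for var in ("age", "bmi"):
        a, b = cases[var].dropna(), controls[var].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=True)
        out[var] = {
            "cases": f"{a.mean():.1f} ± {a.std():.1f}",
            "controls": f"{b.mean():.1f} ± {b.std():.1f}",
            "test": "t",
            "statistic": float(t),
            "p": float(p),
            "n_missing": int(sub[var].isna().sum()),
        }
    for var, label in (("sex", "female_sex"), ("smoking", "smoking")):
        a, b = cases[var].dropna(), controls[var].dropna()
        tab = [[int(a.sum()), int(len(a) - a.sum())], [int(b.sum()), int(len(b) - b.sum())]]
        chi2, p, _, _ = stats.chi2_contingency(tab, correction=True)
        out[label] = {
            "cases": f"{int(a.sum())} ({100 * a.mean():.1f})",
            "controls": f"{int(b.sum())} ({100 * b.mean():.1f})",
            "test": "chi2",
            "statistic": float(chi2),
            "p": float(p),
            "n_missing": int(sub[var].isna().sum()),
        }
    table = pd.DataFrame.from_dict(out, orient="index")
    table.index.name = "variable"
    return table


def two_by_two_chi2(
    yes_a: int, n_a: int, yes_b: int, n_b: int, correction: bool = True
) -> tuple[float, float]:
    """Chi-square test (Yates-corrected by default) on a 2x2 of counts."""
    tab = [[yes_a, n_a - yes_a], [yes_b, n_b - yes_b]]
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=correction)
    return float(chi2), float(p)


def endpoint_rows(cohort: pd.DataFrame, endpoint: str) -> tuple[pd.Series, pd.Series]:
    """Row mask and 0/1 labels for one endpoint.

    ``lifetime``: all subjects, cases = lifetime migraine.  ``active``:
    active cases vs migraine-free controls (lifetime-but-not-active
    subjects are excluded, as active status is defined only within
    lifetime cases).
    """
    if endpoint == "lifetime":
        mask = pd.Series(True, index=cohort.index)
        yy = cohort["lifetime"].astype(int)
    elif endpoint == "active":
        mask = (cohort["active"] == 1) | (cohort["lifetime"] == 0)
        yy = cohort["active"].astype(int)
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return mask, yy[mask]
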