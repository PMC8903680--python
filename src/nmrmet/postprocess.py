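"""Per-signal post-processing in fixed order.

filter (+-4 SD) -> conditional log10 transform -> kinship adjustment ->
Z-score.  Each stage is available on its own; ``postprocess_signals``
runs the full chain over a SignalTable and returns the Z-score matrix
plus a per-signal processing log (cells filtered, transform flag,
kinship method used).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm

from .types import SignalTable

logger = logging.getLogger(__name__)

__all__ = [
    "filter_extremes",
    "normalize_signal",
    "adjust_kinship",
    "zscore",
    "postprocess_signals",
    "intraclass_correlation",
]


def filter_extremes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Set cells outside mean +- 4 SD to NaN.

    Mean and SD are computed once on the input (NaNs ignored); an SD of
    zero filters nothing.  Returns (filtered vector, removal mask).
    """
    x = np.asarray(values, dtype=float).copy()
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    mu = float(np.mean(x[finite]))
    sd = float(np.std(x[finite], ddof=1))
    mask = np.zeros(x.shape, dtype=bool)
    if sd > 0:
        mask[finite] = np.abs(x[finite] - mu) > 4.0 * sd
        x[mask] = np.nan
    return x, mask


def normalize_signal(
    values: np.ndarray,
    alpha: float = 0.05,
    max_test_n: int = 5000,
) -> tuple[np.ndarray, bool]:
    """log10-transform a signal when it is non-normal and right-skewed.

    Normality is judged by a Shapiro-Wilk test (p < ``alpha``) on up to
    ``max_test_n`` values; the transform additionally requires positive
    skewness (log10 only corrects right skew) and all-positive values.
    Returns (possibly transformed vector, transform-applied flag).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("all-missing signal")
    obs = x[finite]
    test = obs if obs.size <= max_test_n else obs[:: int(np.ceil(obs.size / max_test_n))]
    if test.size < 3 or np.ptp(test) == 0:
        return x.copy(), False
    p = stats.shapiro(test).pvalue
    skew = stats.skew(obs)
    if p >= alpha or skew <= 0:
        return x.copy(), False
    if (obs <= 0).any():
        logger.warning("nonpositive values present; log10 transform skipped")
        return x.copy(), False
    out = x.copy()
    out[finite] = np.log10(obs)
    return out, True


def adjust_kinship(
    values: np.ndarray,
    families: np.ndarray,
    method: str = "mixed_model",
) -> tuple[np.ndarray, str]:
    """Remove family-shared variation; return residuals.

    ``mixed_model`` (default): intercept + family random effect
    (block-diagonal relatedness, one block per disjoint family);
    residuals subtract both the fixed mean and the family BLUPs.
    ``family_fixed``: residuals from regression on family indicators
    (equivalently within-family centering).  A singular or failed mixed
    fit falls back to ``family_fixed`` with a warning.  Missing cells
    propagate as NaN.
    """
    x = np.asarray(values, dtype=float)
    fam = np.asarray(families)
    if fam.shape != x.shape:
        raise ValueError("every sample needs a family assignment")
    finite = np.isfinite(x)
    out = np.full(x.shape, np.nan)
    obs = x[finite]
    fam_obs = fam[finite]

    if method == "mixed_model":
        import warnings as _warnings

        # no repeated families -> no estimable family variance: the
        # random effects are zero and the residuals are centered values
        if pd.Series(fam_obs).value_counts().max() == 1:
            out[finite] = obs - obs.mean()
            return out, "mixed_model"
        try:
            groups = pd.Series(fam_obs).astype(str)
            with _warnings.catch_warnings():
                # a signal with no family variance pushes the variance
                # component to the boundary; that is an expected, handled case
                _warnings.simplefilter("ignore")
                model = sm.MixedLM(obs, np.ones((obs.size, 1)), groups=groups)
                fit = model.fit(reml=True)
                # at (or numerically near) zero family variance the BLUPs
                # are zero and the residuals are the centered values; the
                # explicit branch keeps the boundary case deterministic
                var_re = float(np.asarray(fit.cov_re)[0, 0])
                if not np.isfinite(var_re) or var_re <= 1e-8 * max(obs.var(), 1e-300):
                    out[finite] = obs - obs.mean()
                    return out, "mixed_model"
                blups = fit.random_effects
            re = np.array([float(blups[g].iloc[0]) for g in groups])
            out[finite] = obs - fit.fe_params[0] - re
            return out, "mixed_model"
        except Exception as exc:  # singular fit, non-convergence
            logger.debug("mixed model failed (%s); falling back to family_fixed", exc)
            method = "family_fixed"
    if method != "family_fixed":
        raise ValueError(f"unknown kinship method {method!r}")
    s = pd.Series(obs)
    out[finite] = (s - s.groupby(pd.Series(fam_obs).values).transform("mean")).to_numpy()
    return out, "family_fixed"


def zscore(values: np.ndarray) -> np.ndarray:
    """(x - mean) / SD over non-missing cells; SD = 0 is an error."""
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    sd = float(np.std(x[finite], ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("degenerate signal: zero variance")
    out = np.full(x.shape, np.nan)
    out[finite] = (x[finite] - np.mean(x[finite])) / sd
    return out


def intraclass_correlation(values: np.ndarray, families: np.ndarray) -> float:
    """One-way ANOVA (method-of-moments) ICC estimate; test utility."""
    x = np.asarray(values, float)
    df = pd.DataFrame({"y": x, "g": families}).dropna()
    groups = df.groupby("g")["y"]
    k = groups.ngroups
    n = len(df)
    sizes = groups.size().to_numpy(float)
    n0 = (n - np.sum(sizes**2) / n) / (k - 1)
    grand = df["y"].mean()
    msb = float(np.sum(sizes * (groups.mean() - grand) ** 2) / (k - 1))
    msw = float(np.sum((df["y"] - groups.transform("mean")) ** 2) / (n - k))
    var_b = max((msb - msw) / n0, 0.0)
    return var_b / (var_b + msw) if (var_b + msw) > 0 else 0.0


def postprocess_signals(
    table: SignalTable,
    families: pd.Series,
    kinship_method: str = "mixed_model",
    shapiro_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run filter -> transform -> kinship -> Z-score over every signal.

    ``families`` maps sample id to family id and must cover the table.
    Returns (Z-score matrix, per-signal processing log with columns
    n_filtered, log10_applied, kinship_method).
    """
    fam = families.reindex(table.values.index)
    if fam.isna().any():
        raise ValueError("every sample needs a family assignment")
    zcols = {}
    log_rows = {}
    for sid in table.signal_ids:
        raw = table.values[sid].to_numpy()
        filtered, mask = filter_extremes(raw)
        transformed, applied = normalize_signal(filtered, alpha=shapiro_alpha)
        residuals, method = adjust_kinship(
            transformed, fam.to_numpy(), method=kinship_method
        )
        zcols[sid] = zscore(residuals)
        log_rows[sid] = {
            "n_filtered": int(mask.sum()),
            "log10_applied": bool(applied),
            "kinship_method": method,
        }
    z = pd.DataFrame(zcols, index=table.values.index)
    log = pd.DataFrame.from_dict(log_rows, orient="index")
    log.index.name = "signal_id"
    return z, log
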