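"""Family-structured case/control cohort generation.

Emulates an extended-pedigree population study: subjects fall into
disjoint families, covariates have realistic marginals (age and BMI
normal, sex and current smoking Bernoulli) and lifetime case status
follows a logistic model in the covariates whose intercept is solved so
the marginal prevalence matches the configured value.  Active status
(at least one severe attack in the last 12 months) is drawn only among
lifetime cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from ..types import validate_cohort

__all__ = ["CohortConfig", "generate_cohort", "COVARIATE_MARGINALS"]

# population marginals: age/BMI mean and SD, sex/smoking probabilities
COVARIATE_MARGINALS = {
    "age": (48.0, 14.0),
    "bmi": (26.8, 4.7),
    "sex": 0.54,  # P(female); sex = 1 codes female
    "smoking": 0.38,
}


@dataclass
class CohortConfig:
    """Study-design knobs for the synthetic cohort.

    ``covariate_effect_sizes`` are log-odds of lifetime case status per
    standardized covariate unit (age and BMI standardized; sex and
    smoking 0/1).  Defaults reproduce the study's demographic contrasts:
    cases more often female and smoking, slightly younger, BMI null.
    """

    n_subjects: int = 1650
    prevalence_lifetime: float = 0.175
    prevalence_active_given_lifetime: float = 0.52
    covariate_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"sex": 1.2, "age": -0.16, "bmi": 0.0, "smoking": 0.35}
    )
    family_size_mean: float = 8.0
    kinship_variance_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name in ("prevalence_lifetime", "prevalence_active_given_lifetime"):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1]")
        if not 0.0 <= self.kinship_variance_fraction < 1.0:
            raise ValueError("kinship_variance_fraction must lie in [0, 1)")
        if self.family_size_mean < 1:
            raise ValueError("family_size_mean must be >= 1")
        for k, v in self.covariate_effect_sizes.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite effect size for {k}")


def _family_assignments(rng: np.random.Generator, n: int, mean_size: float) -> np.ndarray:
    """Disjoint family blocks with 1 + Poisson(mean - 1) sizes."""
    fams: list[int] = []
    fam = 0
    while len(fams) < n:
        size = 1 + rng.poisson(max(mean_size - 1.0, 0.0))
        fams.extend([fam] * size)
        fam += 1
    return np.asarray(fams[:n])


def standardized_covariates(cohort: pd.DataFrame) -> pd.DataFrame:
    """Age/BMI standardized by their population marginals; sex/smoking 0/1."""
    out = pd.DataFrame(index=cohort.index)
    for c in ("age", "bmi"):
        mu, sd = COVARIATE_MARGINALS[c]
        out[c] = (cohort[c] - mu) / sd
    out["sex"] = cohort["sex"].astype(float)
    out["smoking"] = cohort["smoking"].astype(float)
    return out


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a cohort table; fully determined by ``config.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_subjects

    cohort = pd.DataFrame(
        {
            "subject_id": [f"subj{i + 1:05d}" for i in range(n)],
            "family_id": _family_assignments(rng, n, config.family_size_mean),
        }
    )
    age_mu, age_sd = COVARIATE_MARGINALS["age"]
    bmi_mu, bmi_sd = COVARIATE_MARGINALS["bmi"]
    cohort["age"] = np.clip(rng.normal(age_mu, age_sd, n), 18.0, 95.0)
    cohort["sex"] = rng.binomial(1, COVARIATE_MARGINALS["sex"], n)
    cohort["bmi"] = np.clip(rng.normal(bmi_mu, bmi_sd, n), 15.0, 55.0)
    cohort["smoking"] = rng.binomial(1, COVARIATE_MARGINALS["smoking"], n)

    x = standardized_covariates(cohort)
    eta = np.zeros(n)
    for cov, beta in config.covariate_effect_sizes.items():
        if cov not in x.columns:
            raise ValueError(f"unknown covariate {cov!r}")
        eta += beta * x[cov].to_numpy()

    p = config.prevalence_lifetime
    if p in (0.0, 1.0) or np.allclose(eta, 0.0):
        probs = np.full(n, p)
    else:
        # intercept solved so the marginal prevalence matches the target
        alpha = brentq(lambda a: expit(a + eta).mean() - p, -30.0, 30.0)
        probs = expit(alpha + eta)
    cohort["lifetime"] = rng.binomial(1, probs)
    active = np.zeros(n, dtype=int)
    cases = cohort["lifetime"].to_numpy() == 1
    active[cases] = rng.binomial(1, config.prevalence_active_given_lifetime, cases.sum())
    cohort["active"] = active
    return validate_cohort(cohort)
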