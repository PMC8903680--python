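"""Latent metabolite concentrations with family (kinship) structure.

Per subject i and metabolite m the natural-log concentration is

    log c_im = log(base_m) + beta_m' x_i + delta_m * lifetime_i
               + delta'_m * active_i + b_{f(i),m} + e_im

with family random effect b ~ N(0, rho * sigma_m^2) shared by all
members of subject i's family and individual noise
e ~ N(0, (1 - rho) * sigma_m^2), where rho is the configured kinship
variance fraction (the within-family intraclass correlation) and
sigma_m the template's log_sd.  All signals of one metabolite share its
concentration, which is what makes same-metabolite peak intensities
strongly correlated downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortConfig, standardized_covariates
from .templates import MetaboliteTemplate, signal_catalog

__all__ = ["GroundTruth", "generate_concentrations"]


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must estimate."""

    concentrations: pd.DataFrame  # subjects x metabolites (natural scale)
    catalog: pd.DataFrame  # per-signal row: metabolite, shift, informative flags
    family_assignments: pd.Series  # subject_id -> family_id
    # per-sample acquisition offsets, filled in by render_spectra
    sample_effects: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def lifetime_informative_signals(self) -> set[str]:
        return set(self.catalog.index[self.catalog["lifetime_informative"]])

    @property
    def active_informative_signals(self) -> set[str]:
        return set(self.catalog.index[self.catalog["active_informative"]])

    def true_signal_areas(self) -> pd.DataFrame:
        """Noise-free per-signal areas: concentration x relative area."""
        conc = self.concentrations
        areas = {
            sid: conc[row["metabolite"]] * row["relative_area"]
            for sid, row in self.catalog.iterrows()
        }
        return pd.DataFrame(areas, index=conc.index)


def generate_concentrations(
    cohort: pd.DataFrame,
    templates: list[MetaboliteTemplate],
    config: CohortConfig,
) -> GroundTruth:
    """Draw the subjects x metabolites concentration matrix."""
    if not templates:
        raise ValueError("templates must be non-empty")
    rho = config.kinship_variance_fraction
    if rho < 0:
        raise ValueError("kinship_variance_fraction must be nonnegative")

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    n = len(cohort)
    x = standardized_covariates(cohort)
    lifetime = cohort["lifetime"].to_numpy(float)
    active = cohort["active"].to_numpy(float)
    families = cohort["family_id"].to_numpy()
    fam_ids, fam_index = np.unique(families, return_inverse=True)

    cols = {}
    for t in templates:
        fixed = np.log(t.base_concentration) * np.ones(n)
        for cov, beta in t.covariate_loadings.items():
            fixed += beta * x[cov].to_numpy()
        fixed += t.case_log_fold_change * lifetime
        fixed += t.active_extra_log_fold_change * active
        fam_effect = rng.normal(0.0, t.log_sd * np.sqrt(rho), fam_ids.size)[fam_index]
        indiv = rng.normal(0.0, t.log_sd * np.sqrt(1.0 - rho), n)
        cols[t.name] = np.exp(fixed + fam_effect + indiv)

    conc = pd.DataFrame(cols, index=pd.Index(cohort["subject_id"], name="subject_id"))
    return GroundTruth(
        concentrations=conc,
        catalog=signal_catalog(templates),
        family_assignments=pd.Series(
            families, index=conc.index, name="family_id"
        ),
    )
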