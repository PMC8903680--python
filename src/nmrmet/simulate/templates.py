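"""Metabolite templates for the synthetic serum spectra.

The catalog mirrors the structure of the measured study data: 100
resonance signals from 49 "metabolites" (a metabolite may contribute
several multiplets; all of a metabolite's signals share one underlying
concentration).  The 23 signals of the published lifetime/active
profiles keep their literature chemical shifts (they double as the
shipped reference-assignment table); the remaining 77 signals belong to
28 generic serum metabolites with frozen, collision-free positions.

Case effects are expressed on the log-concentration scale, sized
relative to each metabolite's between-subject log-SD so that the
active-endpoint profile carries a weighted-score effect of roughly one
log-odds unit per score SD at the default cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteTemplate",
    "default_templates",
    "signal_catalog",
    "LIFETIME_PROFILE_METABOLITES",
    "ACTIVE_PROFILE_METABOLITES",
]


@dataclass
class MetaboliteTemplate:
    """One metabolite's resonances and population model.

    peaks : list of (center_ppm, relative_area, width_ppm, eta)
        ``relative_area`` sums to 1 over the metabolite; ``eta`` is the
        Gaussian fraction of the pseudo-Voigt shape.
    base_concentration : geometric-mean concentration (arbitrary units).
    log_sd : between-subject SD of natural-log concentration
        (family + individual components combined).
    case_log_fold_change : additive log-concentration shift in all
        lifetime cases.
    active_extra_log_fold_change : additional shift in active cases
        only, on top of the lifetime effect (active cases are a subset
        of lifetime cases, and the active profile is the stronger one).
    covariate_loadings : additive log-concentration shift per
        standardized covariate unit (age and BMI are standardized; sex
        and smoking are 0/1 indicators).
    """

    name: str
    peaks: list[tuple[float, float, float, float]]
    base_concentration: float = 1.0
    log_sd: float = 0.25
    case_log_fold_change: float = 0.0
    active_extra_log_fold_change: float = 0.0
    covariate_loadings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("template needs at least one peak")
        areas = np.array([p[1] for p in self.peaks], dtype=float)
        if not np.isclose(areas.sum(), 1.0, atol=1e-8):
            raise ValueError(f"{self.name}: relative areas must sum to 1")
        for c, a, w, eta in self.peaks:
            if w <= 0 or not 0.0 <= eta <= 1.0 or a < 0:
                raise ValueError(f"{self.name}: invalid peak parameters")
        if self.base_concentration <= 0 or self.log_sd <= 0:
            raise ValueError(f"{self.name}: concentration model must be positive")


# Chemical shifts (ppm) of the published profile signals.  Glucose is
# listed first so every truncated template subset keeps the anomeric
# calibration anchor.
_PROFILE_SIGNALS: dict[str, list[float]] = {
    "Glucose": [3.72103, 5.22921],
    "Cholesterol": [0.89006],
    "Isoleucine": [0.92847, 0.99919],
    "Unknown-0.95118": [0.95118],
    "Leucine": [0.95702],
    "Lipids (CH2)": [1.26482],
    "Unknown-1.40660": [1.40660],
    "Acetate": [1.90859],
    "Lipids (CH2CH=CH)": [2.22215],
    "Pyruvic acid": [2.36196],
    "Methionine": [2.63742],
    "Dimethylglycine": [2.91618],
    "Unknown-3.35396": [3.35396],
    "1,5-Anhydrosorbitol": [3.58832],
    "Valine": [3.59782],
    "Myoinositol": [3.62232],
    "Creatine": [3.92001],
    "Serine": [3.95567],
    "Creatinine": [4.04386],
    "Proline": [4.12106],
    "Unknown-4.50117": [4.50117],
}

# Metabolites of the 6-signal lifetime profile (effect in all lifetime cases)
LIFETIME_PROFILE_METABOLITES = (
    "Isoleucine",
    "Unknown-1.40660",
    "Methionine",
    "1,5-Anhydrosorbitol",
    "Creatine",
)

# Metabolites of the 22-signal active profile (extra effect in active cases)
ACTIVE_PROFILE_METABOLITES = (
    "Cholesterol",
    "Isoleucine",
    "Unknown-0.95118",
    "Leucine",
    "Lipids (CH2)",
    "Unknown-1.40660",
    "Acetate",
    "Lipids (CH2CH=CH)",
    "Pyruvic acid",
    "Methionine",
    "Dimethylglycine",
    "Unknown-3.35396",
    "1,5-Anhydrosorbitol",
    "Valine",
    "Myoinositol",
    "Glucose",
    "Serine",
    "Creatinine",
    "Proline",
    "Unknown-4.50117",
)

# Direction of the case effect per profile metabolite (amino acids down,
# lipid/glucose-metabolism signals up; mixed signs keep the profile from
# collapsing onto a single latent direction).
_EFFECT_SIGN = {
    "Cholesterol": +1,
    "Isoleucine": -1,
    "Unknown-0.95118": +1,
    "Leucine": -1,
    "Lipids (CH2)": +1,
    "Unknown-1.40660": -1,
    "Acetate": +1,
    "Lipids (CH2CH=CH)": +1,
    "Pyruvic acid": +1,
    "Methionine": -1,
    "Dimethylglycine": +1,
    "Unknown-3.35396": -1,
    "1,5-Anhydrosorbitol": -1,
    "Valine": -1,
    "Myoinositol": +1,
    "Glucose": +1,
    "Creatine": +1,
    "Serine": -1,
    "Creatinine": +1,
    "Proline": -1,
    "Unknown-4.50117": +1,
}

# Covariate loadings (per standardized covariate unit, in units of
# log_sd) for the profile metabolites: lipid-related signals track BMI
# and age, amino acids differ by sex, organic acids track smoking.
_COVARIATE_PLAN = {
    "Cholesterol": {"bmi": 0.20, "age": 0.15},
    "Lipids (CH2)": {"bmi": 0.25, "age": 0.10},
    "Lipids (CH2CH=CH)": {"bmi": 0.20},
    "Isoleucine": {"sex": -0.25},
    "Leucine": {"sex": -0.25},
    "Valine": {"sex": -0.20},
    "Methionine": {"sex": -0.15},
    "Acetate": {"smoking": 0.20},
    "Pyruvic acid": {"smoking": 0.25},
    "Glucose": {"age": 0.20, "bmi": 0.15},
    "Creatinine": {"sex": 0.25},
    "Creatine": {"sex": -0.15},
    "Myoinositol": {"age": 0.15},
    "Serine": {"sex": 0.15},
    "Dimethylglycine": {"smoking": 0.10},
    "1,5-Anhydrosorbitol": {"bmi": -0.10},
    "Proline": {"age": -0.10},
}

# Effect sizes in units of the metabolite's log_sd
_LIFETIME_EFFECT_SD = 0.12
_ACTIVE_EXTRA_EFFECT_SD = 0.22

_N_FILLER = 28
_FILLER_PEAK_COUNTS = [3] * 21 + [2] * 7  # 77 filler signals -> 100 total
_EXCLUDED_WINDOWS = [(4.40, 5.15), (5.15, 5.31)]  # water region, calibration anchor
_PPM_RANGE = (0.72, 8.55)
_MIN_SEPARATION = 0.014


def _filler_centers(rng: np.random.Generator, n: int, occupied: list[float]) -> list[float]:
    centers: list[float] = []
    taken = list(occupied)
    while len(centers) < n:
        c = float(rng.uniform(*_PPM_RANGE))
        if any(lo <= c <= hi for lo, hi in _EXCLUDED_WINDOWS):
            continue
        if any(abs(c - t) < _MIN_SEPARATION for t in taken):
            continue
        centers.append(c)
        taken.append(c)
    return centers


def default_templates() -> list[MetaboliteTemplate]:
    """The frozen 49-metabolite / 100-signal catalog."""
    templates: list[MetaboliteTemplate] = []
    rng = np.random.default_rng(20211124)  # frozen catalog, not run randomness

    base_conc = {
        "Glucose": 5.0,
        "Cholesterol": 3.0,
        "Lipids (CH2)": 4.0,
        "Lipids (CH2CH=CH)": 2.0,
        "Creatinine": 0.8,
        "Acetate": 0.5,
    }
    for name, shifts in _PROFILE_SIGNALS.items():
        k = len(shifts)
        rel = [1.0 / k] * k if k > 1 else [1.0]
        peaks = []
        for s, a in zip(shifts, rel):
            width = float(rng.uniform(0.014, 0.024))
            eta = float(rng.uniform(0.3, 0.8))
            peaks.append((s, a, width, eta))
        log_sd = float(rng.uniform(0.20, 0.32))
        sign = _EFFECT_SIGN[name]
        lfc = sign * _LIFETIME_EFFECT_SD * log_sd if name in LIFETIME_PROFILE_METABOLITES else 0.0
        extra = sign * _ACTIVE_EXTRA_EFFECT_SD * log_sd if name in ACTIVE_PROFILE_METABOLITES else 0.0
        loadings = {
            cov: w * log_sd for cov, w in _COVARIATE_PLAN.get(name, {}).items()
        }
        templates.append(
            MetaboliteTemplate(
                name=name,
                peaks=peaks,
                base_concentration=base_conc.get(name, float(rng.uniform(0.4, 2.5))),
                log_sd=log_sd,
                case_log_fold_change=lfc,
                active_extra_log_fold_change=extra,
                covariate_loadings=loadings,
            )
        )

    occupied = [s for shifts in _PROFILE_SIGNALS.values() for s in shifts]
    covs = ("age", "sex", "bmi", "smoking")
    for i, k in enumerate(_FILLER_PEAK_COUNTS):
        centers = _filler_centers(rng, k, occupied)
        occupied.extend(centers)
        rel = rng.dirichlet(np.full(k, 5.0))
        peaks = [
            (c, float(a), float(rng.uniform(0.014, 0.026)), float(rng.uniform(0.2, 0.9)))
            for c, a in zip(sorted(centers), rel)
        ]
        log_sd = float(rng.uniform(0.16, 0.34))
        # a third of the fillers carry mild covariate structure for realism
        loadings = (
            {str(rng.choice(covs)): float(rng.uniform(-0.12, 0.12)) * log_sd}
            if i % 3 == 0
            else {}
        )
        templates.append(
            MetaboliteTemplate(
                name=f"serum-met-{i + 1:02d}",
                peaks=peaks,
                base_concentration=float(rng.uniform(0.3, 3.0)),
                log_sd=log_sd,
                covariate_loadings=loadings,
            )
        )
    return templates


def signal_catalog(templates: list[MetaboliteTemplate]) -> pd.DataFrame:
    """Flatten templates into one row per signal, ordered by ppm.

    Signal ids ``s001..sNNN`` follow ascending chemical shift.  The
    ``lifetime_informative`` / ``active_informative`` flags mark the
    signals whose metabolite carries the corresponding case effect —
    the ground-truth sets recovery tests score selection against.
    """
    rows = []
    for t in templates:
        for c, a, w, eta in t.peaks:
            rows.append(
                {
                    "metabolite": t.name,
                    "shift_ppm": c,
                    "relative_area": a,
                    "width_ppm": w,
                    "eta": eta,
                    "lifetime_informative": t.case_log_fold_change != 0.0,
                    "active_informative": t.active_extra_log_fold_change != 0.0,
                }
            )
    cat = pd.DataFrame(rows).sort_values("shift_ppm", kind="stable").reset_index(drop=True)
    cat.index = [f"s{i + 1:03d}" for i in range(len(cat))]
    cat.index.name = "signal_id"
    return cat
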