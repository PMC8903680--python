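# nmrmet

Serum ¹H-NMR metabolomics pipeline for case/control profiling in
family-structured cohorts — from frequency-domain spectra through peak
quantification to elastic-net metabolite-profile discovery and
weighted-score inference.

The package targets the analysis design used in population metabolomics
of migraine: serum CPMG spectra and J-resolved (JRES) projections are
quality-controlled, scaled by receiver sensitivity, baseline-corrected,
calibrated on the anomeric α-D-glucose resonance (δ = 5.23 ppm) and
aligned by correlation-optimized warping (COW); JRES-projection peaks
are deconvolved with mixed Gauss–Lorentz (pseudo-Voigt) line shapes by
simplex search, screened with a median ± 3·IQR rule and rescued by a
PLS model from the non-warped spectrum; signal intensities are
filtered at mean ± 4 SD, log₁₀-transformed when non-normal, adjusted
for kinship via a family random-effect model and Z-scored; elastic-net
logistic regression (α = 0.5, 50-fold stratified CV) selects a signal
profile per endpoint (lifetime and active migraine), whose unpenalized
refit defines the weighted metabolite score

&nbsp;&nbsp;&nbsp;&nbsp;score_i = β̂₀ + Σ_j β̂_j · Z_ij

reported with odds ratios, Nagelkerke R², Hosmer–Lemeshow calibration
and a likelihood-ratio test against an age/sex/BMI/smoking-only model.
Because the cohort data underlying this design are not public, a
first-class synthetic-data module generates family-structured cohorts
(default n = 1650, 17.5% lifetime prevalence, 52% of cases active), 100
resonance signals from 49 metabolites, and rendered spectra with full
ground truth, so every stage is testable against known truth.

## Worked example

```python
from nmrmet.config import RunConfig
from nmrmet.pipeline import model_stage, postprocess_stage
from nmrmet.simulate import (default_templates, generate_cohort,
                             generate_concentrations, measured_signal_table)

cfg = RunConfig(seed=7)
cfg.cohort.seed = 7
templates = default_templates()
cohort = generate_cohort(cfg.cohort)                      # 1650 subjects, 199 families
truth = generate_concentrations(cohort, templates, cfg.cohort)
table = measured_signal_table(truth, seed=7)              # 1650 x 100 intensities
z, log = postprocess_stage(cfg, table, cohort)            # Z-scores, kinship-adjusted
reports, demo, cov = model_stage(cfg, z, cohort)
r = reports["active"]
print(len(r.selected_signals), round(r.odds_ratio, 2), round(r.r2_unadjusted, 3))
```

prints

```
49 2.72 0.366
```

— the elastic net selects 49 of 100 signals for the active endpoint
(including 21 of the 22 truly informative ones), and the weighted
metabolite score carries an in-sample odds ratio of 2.72 per unit
(exactly e: regressing case status on its own fitted linear predictor
always returns slope 1, which is why in-sample score ORs cluster at
2.72), explaining 36.6% of the variance (Nagelkerke R²) in this
synthetic cohort.  After adjustment for age, sex, BMI and smoking the
association remains (likelihood-ratio p ≈ 4 × 10⁻⁵⁴ here).

The numbered scripts under `analysis/` run the same study as a
pipeline narrative — `01_simulate.py` (cohort + rendered spectra),
`02_preprocess.py` (QC through COW), `03_quantify.py` (deconvolution,
PLS rescue, assignment), `04_postprocess.py`, `05_model.py`,
`06_report.py` — each writing its tables under `results/`.  The same
stages are available as CLI subcommands (`nmrmet simulate`, `nmrmet
preprocess`, …, `nmrmet run`).

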