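# Methods

This note documents the models and numerical choices behind `nmrmet`:
what each stage assumes, which knobs matter, what the synthetic data
do and do not emulate, and where the design was genuinely open.

## Synthetic study design

The generator stands in for a non-public family-cohort serum NMR
study; its defaults are the study conditions, not tuning knobs.

**Cohort.** `CohortConfig` defaults: n = 1650 subjects in disjoint
families (sizes 1 + Poisson(7), ≈ 200 families), lifetime case
prevalence 0.175, active-given-lifetime 0.52 (active = at least one
severe attack in the last 12 months; defined only within lifetime
cases).  Covariates: age ~ N(48, 14²) years, BMI ~ N(26.8, 4.7²),
female sex Bernoulli(0.54), current smoking Bernoulli(0.38).  Lifetime
status follows a logistic model in standardized covariates (log-odds
per unit: sex +1.2, age −0.16/SD, smoking +0.35, BMI 0) whose
intercept is solved by root-finding so the marginal prevalence matches
the target; this reproduces the demographic contrasts of the target
population (cases more often female and smoking, slightly younger, BMI
null).

**Concentrations.** 49 metabolites contribute 100 resonance signals;
all signals of a metabolite share one concentration.  Per subject and
metabolite, log-concentration = log(base) + covariate loadings + case
effect (lifetime cases) + active extra effect (active cases only) +
family random effect + individual noise.  The family component carries
a configurable fraction of the log-variance (`kinship_variance_fraction`,
default 0.3 — the within-family intraclass correlation).  Case effects
are expressed in units of each metabolite's log-SD: 0.12 on the five
lifetime-profile metabolites (six signals) and an additional 0.22 on
the twenty active-profile metabolites (twenty-two signals), with mixed
signs (amino acids decreased, lipid/glucose-metabolism signals
increased).  These sizes were chosen once so the optimal linear score
over the active profile carries roughly one log-odds unit per score SD
(Mahalanobis argument: √(5·0.34² + 15·0.22²) ≈ 1.1); the in-sample
refit estimate is larger because self-refit inflates it.  Two nested
endpoints require one field beyond a single case effect; the template
carries `case_log_fold_change` (all lifetime cases) and
`active_extra_log_fold_change` (active cases only), making the active
profile the stronger, larger one.

**Spectra.** Each signal is an additive pseudo-Voigt
A·[η·Gauss + (1−η)·Lorentz] with shared center and FWHM; area is
concentration × relative area, and the analytic area
A·w·[η·√(π/4ln2) + (1−η)·π/2] is the quantification target.  The
default grid runs 9.0 → 0.5 ppm at 0.001 ppm (descending, NMR
convention), putting ≥ 8 points across the narrowest rendered JRES
peak — the resolution floor for stable deconvolution.  Per sample the
generator injects: a global ppm offset (SD 0.003 ppm), a receiver gain
inversely proportional to a drawn pulse length times lognormal noise
(CV 5%), a constant baseline offset (SD 0.05), a broad residual water
resonance at 4.70 ppm, and iid Gaussian noise (SD 0.01 for CPMG, half
that for the JRES projection, whose widths are scaled by 0.55 to mimic
the collapse of J-multiplets).  Peaks are evaluated analytically at
their jittered centers rather than shifting a rendered spectrum by
interpolation; interpolation smoothing would otherwise contaminate the
line shapes the deconvolution assumes.

**What the generator does not emulate.** FIDs, phasing errors,
pH-dependent *local* shift variation (the injected offset is global
per sample), baseline curvature, peak-shape distortions from imperfect
shimming, and pedigree loops (families are disjoint blocks).  Passing
tests therefore demonstrate correctness of the pipeline's algorithms
under its own model assumptions — not robustness to every artifact of
real spectra.  In particular, because misalignment is global and
calibration removes it, COW contributes little on synthetic data and
its slight area distortion (segment stretching) is visible as a ~2%
per-sample effect.

**Quantification-equivalent route.** For cohort-scale statistical
experiments, `measured_signal_table` returns true areas under
multiplicative lognormal error (CV 5%, the empirical accuracy of the
deconvolution + alignment chain at rendered SNR).  Spectral stages are
validated on rendered batches of ~40 samples; simplex-deconvolving
1650 full-resolution spectra adds cost, not information, to the
modeling questions.  The problem sizes used throughout (40-sample
spectral batches, n = 1650 statistical experiments, 200-replicate
calibration checks) are the package's scaling choices.

## Spectral processing

- **QC** uses the acquisition metadata: reject when residual-water
  intensity exceeds 5× the batch median or the linewidth proxy exceeds
  2.5 Hz (thresholds config-exposed; the original criteria are not
  quantified anywhere, so defaults were set to separate the
  generator's corrupted samples cleanly from its nominal ones).
- **Receiver scaling** multiplies intensities by pulse length over a
  reference pulse length (sensitivity ∝ 1/pulse length).
- **Baseline** subtracts the median intensity over signal-free windows
  (defaults 8.70–9.00 and 0.52–0.68 ppm).  A constant cannot absorb
  accumulated Lorentzian tails; that residual is handled later by the
  per-window linear baseline in deconvolution.
- **Calibration** finds the anomeric α-D-glucose apex within
  ±0.05 ppm of 5.23 ppm (largest local maximum above a median + 5·MAD
  floor), refines it by 3-point parabolic interpolation, and shifts
  the axis so the apex sits at 5.23; spectra are then re-interpolated
  onto the master grid with a cubic spline (linear interpolation
  attenuates narrow peaks by several percent at this sampling
  density, biasing downstream areas).  Calibration is idempotent.
- **COW alignment** warps each spectrum to the point-wise median of
  the QC-passed batch.  The reference axis is cut into ~50-point
  segments; sample boundaries may deviate by ≤ 5 points per segment
  (cumulative slack bound, optionally capped at ±10 points overall —
  calibration has already removed global shifts, so larger drifts are
  spurious).  Each candidate segment is linearly interpolated onto the
  reference segment length and scored by Pearson correlation
  (zero-variance segments contribute 0); dynamic programming maximizes
  the summed score.  Ties resolve to the smallest cumulative absolute
  boundary displacement, then to the smallest boundaries compared from
  the last internal boundary backwards — the DP is verified against
  exhaustive enumeration on small instances.  The same warp is applied
  unchanged to the paired JRES projection.
- **JRES handling**: rows of the 2-D matrix are shifted by
  0.4992·(R/2 − k) points (k 1-based; linear interpolation, zero fill),
  the matrix is symmetrized by averaging mirrored rows (averaging
  chosen over minima — the gentler of the two common conventions), and
  the sum projection over the indirect dimension yields the 1-D trace
  used for quantification.

## Peak quantification

Peaks with overlapping ±0.02 ppm windows form clusters.  Before
fitting, the estimated tails of all out-of-cluster peaks (library
shapes, apex heights read off the data) are subtracted from the
window, and each cluster is modeled as pseudo-Voigt peaks plus a local
*linear* baseline — with only a constant, sloping Lorentzian tails of
large neighbours bias small-peak areas by tens of percent.  The
optimizer is bounded Nelder–Mead simplex in box-normalized coordinates
(mixed ppm/intensity scales otherwise wreck the simplex geometry),
started from linear-least-squares amplitudes, restarted from its own
optimum until improvement stalls, and from jittered starts on
non-convergence; never-converged peaks are flagged `fit_failed`.
Clusters of ≤ 2 peaks are fitted jointly; larger clusters by
Gauss–Seidel sweeps of per-peak subfits.  Centers and widths are
bounded near their peak-library values, and the Gaussian fraction η is
held at its library value by default (`fit_eta=True` frees it): η is a
property of the instrument and processing chain, and at moderate SNR
even the global least-squares optimum with free η misses overlapping
areas by 5–10% because Gaussian and Lorentzian tails integrate very
differently.  Reported intensity is the analytic area.

Per signal across samples, cells farther than 3·IQR from the median
are discarded (hinges = medians of the half-samples excluding the
sample median when the length is odd; a zero IQR discards only
strictly positive distances, so constant vectors survive).  A PLS
model (default 10 components, reduced with a warning when complete
training rows are scarce) trained on fully-fitted samples maps the
non-warped spectrum directly onto all intensities; discarded and
failed cells are replaced by its predictions (`pls_predicted`), never
fed back into training.  Signals are assigned the nearest
reference-table metabolite within tolerance (0.01 ppm); signals mapped
to the same named metabolite must correlate pairwise at ≥ 0.5 across
samples (they share a concentration) or the later-listed one reverts
to unknown.  Placeholder `Unknown` reference rows are exempt — they
are unidentified resonances, not a claim of shared identity.

## Signal post-processing

Fixed order per signal: (1) filter cells outside mean ± 4 SD (moments
computed once on the input; SD 0 filters nothing); (2) log₁₀-transform
iff Shapiro–Wilk p < 0.05 on ≤ 5000 values *and* skewness is positive
*and* all values are positive (log₁₀ only corrects right skew; the
criterion is config-exposed since the original procedure names no
test); (3) kinship adjustment: a family random-intercept mixed model
(REML), residuals subtracting both the fixed mean and the family
BLUPs.  Full pedigrees are out of scope; the family-block model
captures exactly the variance structure the generator creates.  At or
numerically near zero family variance the BLUPs are zero and residuals
are centered values — branching on the estimate keeps the boundary
deterministic; other failures fall back to regression on family
indicators (within-family centering) with a warning; (4) Z-scores over
non-missing cells (full cohort, not controls only).  Missing cells
propagate; complete-case handling is deferred to modeling.  Note the
chain is rank-preserving per signal only in the absence of family
structure: kinship residualization subtracts family-specific means and
legitimately reorders values.

## Profile modeling

Elastic-net logistic regression in glmnet's parameterization (mean
half-deviance + λ[α‖β‖₁ + (1−α)/2‖β‖²], α = 0.5) over a 25-point
log-spaced λ path from the null-gradient λ_max down to λ_max/500,
solved by warm-started saga (seeded; equivalence with glmnet at fixed
λ is tested).  Cross-validation is seeded stratified k-fold (k = 50;
with ~150 cases that is ≈ 3 cases per fold, and stratification
prevents empty-case folds); a repeated-subsample mode (stratified
90/10 splits) is available behind `cv_mode="subsample"` since the
original description is ambiguous between the two.  λ is chosen at the
minimum mean CV deviance (λ_min; λ_1se also reported).  Selection uses
rows complete on all signals; the unpenalized refit on the selected
signals uses rows complete on those signals only, mirroring the
complete-case logic of the target design.  Perfect separation in the
refit falls back to a lightly ridge-penalized fit and is flagged.

The refit's linear predictor is the weighted metabolite score.  A
second logistic model of status on the score (Wald 95% CIs; the
in-sample OR per unit score is exactly e by construction), optionally
plus age, sex, BMI and smoking, reports Nagelkerke
R² = [1 − exp(2(ll₀ − ll)/n)]/[1 − exp(2·ll₀/n)], Hosmer–Lemeshow over
deciles of fitted risk (ties kept together; zero-variance groups
merged with df reduced; fewer than 3 usable groups yields NaN), and
the likelihood-ratio (ANOVA-style) test of the full model against
covariates only.  Covariate influence on the score is assessed by
per-covariate and joint linear models plus stratified score means
(sex, smoking, age and BMI tertiles).  Demographics tables use pooled
two-sample t-tests for continuous variables and Yates
continuity-corrected chi-square for 2×2 tables — the corrected variant
reproduces the printed three-decimal p-value of the reference
demographics table where the uncorrected one does not.

## Known limitations

- In-sample score inference is optimistic by construction (selection
  and evaluation share the cohort); the package reproduces the
  procedure and its caveats, not valid p-values.
- Heavily overlapped signal pairs (separation ≲ 0.7 FWHM) are not
  individually identifiable at any optimizer quality; their areas
  trade off while the pair total is conserved.  Such signals carry a
  stable per-signal bias that Z-scoring absorbs.
- COW's piecewise stretching perturbs areas by up to a few percent
  when boundary moves are noise-driven; with per-sample global shifts
  already removed by calibration this is its dominant effect on
  synthetic data.
- The mixed model treats families as exchangeable blocks; real
  pedigree relatedness (varying kinship coefficients within a family)
  is approximated by a single family variance component.
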