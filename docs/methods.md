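# Methods

This note documents the statistical models the package implements, the
choices made where the underlying methodology leaves room, and what the
synthetic cohort generator does and does not emulate.

## The analysis problem

The package targets longitudinal two-group EEG cohort designs: an exposed
group (labelled `PEM`, after protein-energy malnutrition cohorts) and
matched controls (`CON`), each measured at two widely separated waves
(childhood, 5–11 years; middle adulthood, 45–51 years) with resting-state
EEG on the 19-channel 10–20 montage, ordinal expert ratings of the same
recordings by two evaluators, and a cognition screen at the adult wave.
Two biomarker families are derived and compared:

* **spectral qEEG** — per-channel log power spectra standardized against
  age-regression norms (the z-scalp spectra), reduced to a latent score
  (`qNPS`) through stability-selected features;
* **semi-quantitative EEG** — ordinal rating items quantified through a
  polytomous IRT model into a latent neurophysiological-status score
  (`sqNPS`, averaged over evaluators to `sqNPS⊙`).

## Spectral pipeline

Epochs are fixed at 2.56 s (256 samples at 100 Hz, 512 at 200 Hz), taken
consecutively without overlap; a record must supply at least 20 clean
epochs (24 is typical for one minute of artifact-free EEG) or it is
rejected with the subject flagged.  After average-referencing, each epoch's
rectangular-window periodogram `|Σ_t x_t e^{-2πikt/N}|²/N` is averaged over
epochs and restricted to 48 bins at k·0.390625 Hz, k = 2…49
(0.78125–19.140625 Hz); the epoch length makes these exact DFT bins at both
sampling rates.  Natural logs are used throughout so that a multiplicative
amplitude change is an additive offset.

The normative model regresses, per (channel, bin), mean log power on a
quadratic in ln(age), with a homoscedastic residual SD per cell.  This is
the simplest form that spans both waves of the design; published norm
libraries use richer forms, and the model object isolates that choice
behind `predict_mean`/`sigma_`.  The Global Scale Factor of a record is
the grand mean over all cells of (log s − μ(age)) — the least-squares
estimate of a common log-scale offset — and
`z = (log s − GSF − μ)/σ`.  By construction z is invariant to rescaling
the raw signal (amplifier/hardware gain), and the mean of the corrected
deviations is exactly zero.  In the full pipeline the norms are fitted on
the control group's observations across both waves; with ~200 reference
records the per-cell z of the reference population has mean ≈ 0 and SD
within [0.85, 1.15].

## IRT latent scores

Ratings follow the grand-total EEG item catalogue (background frequency
0–2, diffuse slow activity 0–3, reactivity 0–2 — adult wave only, focal
abnormality 0–5, paroxysmal activity 0–3, sharp waves 0–2).  The
generalized partial credit model gives
`P(k|θ) ∝ exp(Σ_{v≤k} a_j(θ − b_{jv}))`.  Estimation is marginal maximum
likelihood under a N(0,1) latent prior with 61-node Gauss–Hermite
quadrature, maximized directly with L-BFGS (at this item count EM buys
nothing); standard errors come from a central-difference observed
information matrix.  Orientation is normalized so the summed discrimination
is positive (higher score = more abnormality) and the flip is recorded in
the model metadata.  Loadings use the logistic-to-normal convention
λ = a*/√(1+a*²), a* = a/1.702.  Latent scores are EAP (posterior means on
the quadrature grid); missing items are marginalized, never imputed.

Model optimization mirrors the standard workflow: fit the common-item
model, drop an item whose loading shows it carries no shared signal, and
collapse response categories the evaluators barely use, then compare
AIC/BIC.  Note that dropping an item changes the response set, so these
criteria compare workflows rather than nested models on identical data —
the comparison is the field's practice and is reported as such.

The cognition subscales (seven, scored like the MoCA with maximum total
30) are reduced with the same GPCM machinery to a factor `MF`; its
orientation (higher = better cognition) is opposite to the abnormality
orientation of sqNPS, so association coefficients between the two are
expected negative.

## Stable sparse classification

Per repetition (default 1000): draw a stratified 70% training set, screen
features by pooled two-sample t (|t| ≥ 2 ≈ p < 0.05; a zero-within-class-
variance feature with distinct means is a perfect separator and is kept),
then fit an elastic-net logistic regression (mixing 0.5; penalty chosen by
stratified 5-fold CV over C ∈ {0.01, 0.1, 1, 10} on log-loss) on the
screened training features; a feature is "selected" when its coefficient is
nonzero.  Screening inside each repetition prevents leakage into later
evaluation.  Features selected in more than 50% of repetitions form the
stable set.  An independent round of stratified 70/30 splits refits the
model on the stable set and yields the AUC distribution (mean ± SD), a
pointwise-median ROC on the FPR grid 0:0.01:1, and a Gaussian KDE
(Silverman bandwidth) of the AUC samples.

A calibration caveat that matters for interpreting null behaviour: because
every repetition resamples the *same* finite dataset, a pure-noise feature
whose in-sample group difference happens to be large (|t| ≈ 3) survives
most 70% draws and can exceed the 50% retention threshold.  The
probability that a null dataset contains such a feature grows with the
feature count: measured empty-stable-set rates at n = 60 were ≈ 0.93 (5
features), 0.80 (10), 0.63 (20), 0.67 (30 at 40 reps).  The stable set is
therefore reliably empty under the null only for small feature tables;
for wide tables the retention rule controls the *number* of false stable
features rather than guaranteeing none.

The `qNPS` factor is the first principal axis of the standardized stable
spectral features, with scores standardized and the sign oriented to
correlate positively with sqNPS⊙ when available.

## Mixed-model inference

The univariate model is
`sqNPS ~ 1 + group + age + group:age + sex + ecology` with a subject
random intercept, optionally crossed with an evaluator random intercept
(two levels), fitted by ML so likelihood-ratio comparisons across
fixed-effect structures are valid.  statsmodels' MixedLM is the engine;
the crossed model uses the single-group variance-components formulation
and a Powell/L-BFGS pair of starts because gradient-only optimization is
unreliable at a boundary (evaluator variance 0).  Reported CIs are
estimate ± 1.96·SE.

The multivariate (two-outcome) model stacks `qNPS` and `sqNPS⊙` in long
format with a modality indicator; fixed effects are modality-specific, the
two subject random intercepts have an unstructured 2×2 covariance, and
each modality keeps its own residual variance.  statsmodels cannot fit
per-modality residual variances, so the package implements the ML fit
directly: the five variance parameters (two log residual variances, the
Cholesky factor of the 2×2 covariance) are optimized numerically with the
fixed effects profiled out by GLS, subjects grouped by missingness pattern
for vectorization.  Starting values are moment-based; L-BFGS is followed
by a Nelder–Mead polish (skippable via `precision="fast"` for simulation
studies — the two agree to ~1e-4 on the datasets tested).  Constrained
variants zero every non-intercept fixed effect of the suppressed modality
but keep both intercepts and the full variance structure, so the three
fits share one likelihood scale with an interpretable 5-df difference.
The equal-residual-variance special case is cross-checked against
statsmodels MixedLM in the test suite.

Null calibration of the 5-df likelihood-ratio test is asymptotic: at 30
subjects the measured type-I error runs slightly above 5% (mean L ratio
≈ 5.5); at 80 subjects it is ≈ 6% with mean L ≈ 5.07.  Calibration
studies therefore use ≥ 80 subjects per simulated dataset.

Association analyses regress the cognition factor on each wave's
evaluator-averaged sqNPS with ecology, sex, and age as covariates;
outcome and continuous predictors are z-scored so the coefficients are
standardized betas.  Demographic baseline tests use the pooled-variance
two-sample t for continuous variables and the Pearson chi-squared without
continuity correction for 2×2 tables (these reproduce the published
worked examples: t = 0.81 for age, χ² = 0.11 for sex, 0.49 for
handedness); a Yates-corrected variant is exposed.

## Sensitivity to non-ignorable dropout (ISNI)

For wave-2 dropout, the selection model is logistic in observed covariates
plus γ times the (possibly unobserved) wave-2 outcome — the average of the
subject's missing rows when two evaluator rows are missing.  The index is
the first-order displacement of each fixed-effect ML estimate in γ at
γ = 0:

    ISNI = M⁻¹ Σ_{dropped} (1 − h_i) d_i
    M    = Σ_i X_oi' V_oi⁻¹ X_oi
    d_i  = x̄_mi − X_oi' V_oi⁻¹ V_omi 1/m_i

with h_i the fitted dropout probability and V blocks built from the
ignorable fit's variance components.  Variance components are held at
their ignorable ML values, and the verification oracle
(`profile_estimate_at_gamma`, which maximizes the actual joint
selection-model likelihood by Gauss–Hermite integration over the missing
outcome) makes the same choice, so the finite-difference check is exact to
first order; measured agreement is well within 10% at ε = 0.01.  The
standardized statistic c = |σ·SE/ISNI| is invariant to outcome rescaling;
c ≥ 1 is flagged as robust, and complete data give ISNI = 0, c = ∞.

The default dropout-model covariates are intercept + group + wave-1
outcome, matching the substantive MAR analysis.  When *contrasting*
outcome-driven (MNAR) against random (MCAR) dropout, note that a
covariate-rich dropout model absorbs predictable dropout into h_i and
shrinks the weights (1 − h_i) exactly for the subjects that drive the
contrast; the intercept-only selection model isolates outcome-driven
dropout, and it is the configuration under which MNAR-generated cohorts
show larger median |ISNI| for the group effect than MCAR cohorts.

## The synthetic cohort generator

The generator exists so every downstream stage is testable without human
data.  A latent abnormality trait drives all modalities:

    θ_{i,wave} = shift·1[PEM] + age_slope·age + b_i + e_{i,wave}

with subject effect b_i and wave noise e scaled so the trait has SD 1 in
controls at fixed age (subject_sd² = 0.7, wave_sd² = 0.3 — a
test–retest-stable trait).  Defaults: shift 0.7 SD and age slope 0.01/yr
(magnitudes mirroring the published mixed-model coefficients, with the
positive orientation "higher = more abnormal"), evaluator noise SD 0.3,
two evaluators, 65 subjects per group, wave-2 retention 0.65 — the scale
of the motivating cohort.  Groups are matched pairwise on age, sex and
handedness; the ecology (standard of living) covariate is standardized to
mean 0/SD 1 after a −1.2 SD shift for the exposed group.

EEG is synthesized in the frequency domain as spatially equicorrelated
(ρ = 0.6) colored-noise mixtures: a one-over-f background (exponent 1), a
Gaussian alpha bump (10 ± 1 Hz), and a theta bump (5.5 ± 1.5 Hz) whose
power scales with (1 + theta_gain·θ), theta_gain 0.3, plus a per-record
log-amplitude offset (SD 0.1) that the GSF correction must remove.  This
suffices to exercise the spectral contracts (grid, referencing, norms,
z-scoring, feature screening); it does not emulate artifacts, alpha
reactivity, nonstationarity, or realistic cross-channel topography, so
passing tests say nothing about artifact robustness on real recordings.

Ratings are generated from the GPCM run generatively at θ plus
evaluator-specific noise; the per-item uniform draws are shared across
evaluators so that zero evaluator noise yields identical tables.  Rarely
used top categories (sharp waves, paroxysmal activity) arise from high
step thresholds, which is what makes the category-collapsing workflow
meaningful on synthetic data.  Cognition subscales come from a trait
defined as −0.5·θ_adult plus noise (unit variance), so sqNPS→cognition
associations are negative by construction.

Wave-2 dropout is logistic: intercept only (MCAR); + group + wave-1 trait
(MAR, both coefficients −0.3); + γ·wave-2 trait (MNAR).  The intercept is
solved numerically so the marginal retention matches the target, and the
per-subject uniforms are drawn before the mechanism branch, making MNAR
with γ = 0 bit-identical to MAR under the same seed.

## Problem sizes used in checks

The acceptance script and test suite scale simulation studies to run on a
single CPU: GPCM recovery at n = 1000 (4 items) and the model-optimization
comparison over 50 seeds at n = 300; classifier calibration at n = 60
(null, 10 features) and n = 200 with 10 planted features among 200 (200
repetitions / 200 cross-validations); mixed-model coverage over 500
simulated cohorts of 120 subjects and LRT calibration over 400–500 cohorts
of 80 subjects; ISNI verification at n = 50 with 35% dropout and 50-seed
MNAR/MCAR contrasts at n = 80; and an end-to-end pipeline run at 30
subjects per group, 20 epochs, 25 classifier repetitions, executed twice
to confirm byte-identical artifacts.  The pipeline's own defaults remain
at the motivating cohort's scale (65 per group, 24 epochs, 1000
repetitions).

## Known limitations

* The normative model is quadratic in ln(age) with age-constant σ; real
  norm libraries are richer and may use log10 units.
* The MLME assumes residual independence given the modality-specific
  random intercepts; within-subject×wave residual cross-correlation
  between modalities is not modelled.
* The stable-set null guarantee degrades with feature count (see above).
* ISNI is restricted to wave-2 outcome missingness (the attrition pattern
  of the motivating design) and to the linear mixed model.
* The EDF writer is out of scope; EEG travels as epoch tables (CSV), with
  EDF reading available through the optional mne dependency.
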