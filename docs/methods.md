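# Methods

This note records the modelling choices, default parameters, and known
limitations of the package, in the order the pipeline runs.

## Synthetic cohort generator

The generator emulates the structure of a prospective, population-based
aging cohort measured at 5-year waves (T1–T6) with entry ages 35–80 on a
5-year grid. Time is discrete at wave resolution throughout: every hazard
is a per-wave conditional probability, because the emulated study design
measures everything at 5-year intervals. Consequences of that choice:
events are placed at the diagnosis wave (no backdating of onset between
waves), and an interval's competing outcomes are drawn as one categorical
draw, so a subject never records dementia and death at the same wave —
death after dementia occurs from the dementia state in a later interval.

**Trajectory mixture.** Subjects belong to one of three latent classes —
accelerated (18%), average (60%), stable (22%) — that share all baseline
covariate distributions and differ only in slopes, so class-wise mean
baseline risk is approximately equal by construction. Default annual
drifts (SBP mmHg/yr, BMI kg/m²/yr): accelerated 2.2 / 0.16, average
0.8 / 0.05, stable 0.0 / 0.0, plus per-wave incidences of diabetes
onset, medication start, and smoking changes that rise with class. The
emulated study reports no per-class slope magnitudes, so these are
calibrated package defaults, documented here and in the config, chosen to
yield visibly separated risk trajectories from shared baselines.

**Multistate events.** Transitions healthy→AD, healthy→VaD,
healthy→death, dementia→death with per-wave base probabilities (0.003,
0.002, 0.008, 0.15) and multiplicative effects of class, old age
(≥70: ×10 on healthy-origin transitions), and APOE ε4 (×3, AD only).
Dementia events require age > 65 at the event wave (configurable;
`GeneratorConfig.null()` disables all multipliers and the age floor for
covariate-free cohorts). Defaults were calibrated once so that a
default cohort reproduces the emulated study's magnitudes: roughly 29%
AD, 11% VaD and 45% deaths among subjects entering at ≥70, and a few
percent of the full cohort developing dementia.

**Dropout (nonignorable).** Per-wave dropout applies to subjects alive
and still enrolled at that wave, with conditional rates 1.5% (T3), 6%
(T4), 30% (T5), 39% (T6). Subjects with a later latent dementia or death
event drop out at exp(0.7) ≈ 2× the odds-scale rate of the others; the
two rates are balanced analytically so the *marginal* per-wave rate
equals the configured one in expectation. Deaths are not dropouts: a
death is recorded, a dropout censors all observation from its wave on.

**Item-level missingness (MAR).** Each risk-factor cell is masked with a
base probability (5–6% for SBP/BMI, 2–3% for the binaries) scaled by
observed age (≥70: ×1.5) and sex (female: ×1.2) only, so the mechanism
is missing-at-random given always-observed covariates.

**Episodic memory.** The composite is the exact sum of five task scores
(weights 16/16/16/16/12 of 76), clipped to [0, 76]; at baseline it has
mean ≈35, SD ≈12. Trajectories combine a common age slope (−0.30/yr
around age 60), a *between-subject* slope heterogeneity (SD 0.6/yr) —
without it essentially nobody crosses a pooled-SD decline threshold and
decline events degenerate to a handful of extreme cases — an excess
decline of −0.30/yr in the accelerated class, a −6 point shift after a
dementia diagnosis, and measurement noise (SD 3).

**What the generator does not emulate.** Clinical adjudication and
diagnostic error; practice effects and task-level memory structure;
continuous-time event dynamics within waves; time-varying confounding;
cohort effects between recruitment samples. Passing tests therefore show
that the *estimators* recover known data-generating mechanisms of this
structural form, not that real cohort data meet the estimators'
assumptions.

## Framingham risk function

The office-based (BMI, non-laboratory) general-CVD function with
sex-specific coefficients, baseline survival, and mean linear predictor
shipped as a versioned JSON constants file
(`src/cvdtraj/data/framingham_office_bmi.json`), verified against an
independent step-by-step evaluation of the published coefficient table
(reference profiles frozen in the test suite to 4 decimals). No age
capping is applied outside the 30–74 derivation range; evaluation there
is flagged with a warning. Each wave is scored with that wave's
treatment status. Cutoff groups assign both boundary values (6%, 20%) to
the medium bin, reading "<6%, 6–20%, >20%" literally.

## Trajectory classification

Per-subject OLS slope of risk against years since baseline, using only
pre-diagnosis waves and requiring ≥2 values (fewer → *unclassified*,
retained in outputs rather than dropped). "In relation to age and
baseline risk" is operationalized as linear residualization of raw
slopes on baseline age and baseline risk across subjects; the residuals
are classified. Population moments come from a pattern-mixture
decomposition over dropout patterns (last observed wave): weighted
within-pattern means, and the law of total variance for the SD — exact
reduction to the plain mean/SD under a single pattern. Classification
uses strict inequalities at mean ± 1 SD.

Limitation: because risk growth is multiplicative in level and age,
linear residualization leaves some heterogeneity; with the full 35–80
entry-age span even noiseless class slopes yield ≈85–89% recovery. The
recovery benchmark therefore uses a midlife (40–60) entry scenario with
no measurement noise and no binary risk-factor churn, where recovery
exceeds 93%.

## BART

Self-contained sum-of-trees sampler. Defaults follow the canonical
formulation: 50 trees, split prior α=0.95, β=2.0, leaf scale k=2.0
(continuous outcomes scaled to [−0.5, 0.5], leaf SD 0.5/(k√T); probit
leaf SD 3/(k√T) with an offset at the probit of the base rate), error
variance prior (ν=3, q=0.90), proposal mix grow/prune/change =
0.25/0.25/0.50, up to 100 quantile cutpoints per feature. There is no
swap proposal: grow/prune/change is a correctness-equivalent, simpler
move set. All randomness flows from one seeded generator; a fit is
bit-reproducible given (data, config), and posteriors serialize to JSON
with exact float round-trip.

The Metropolis–Hastings implementation was validated against exact
posterior enumeration on one- and two-split tree spaces (split
probabilities and predictive means agree to ~3 decimal places over long
chains); a frozen version of that check lives in the test suite. One
behaviour worth knowing: under a null (no-signal) binary outcome, probit
BART's pointwise posterior-mean probabilities wiggle up to ~±0.15 around
the base rate at n=1000, because the fixed unit latent variance lets
trees chase binomial cell noise; the *averaged* (standardized)
quantities downstream are well calibrated, which is what the null
calibration suite checks.

## Multistate decomposition and curves

Person-period expansion uses the half-open convention: interval k covers
(wave k, wave k+1]; a subject contributes to a transition at interval k
while occupying its origin at wave k with wave k+1 observed. Competing
transitions from one origin are fitted as *separate* binary probit-BART
models (the decoupling approach); at curve-composition time a draw's
summed exit probabilities are renormalized only if they exceed 1 (rare,
logged). Covariates are frozen at baseline; the interval index enters as
a feature so hazards are freely time-varying. Curves are composed by
forward recursion per posterior draw; cumulative incidence of a state is
its cumulated inflow, and deaths-direct-from-healthy are tracked
separately so the competing-risk decomposition (survivor mass +
cause-specific first-event incidences = 1) is testable to 10⁻⁹.

The principal oracle is the discrete-time Aalen–Johansen-type estimate
built from crude per-interval event fractions: on covariate-free data the
BART-based curves agree with it within ±0.03 at every wave (and the
crude estimator itself is cross-checked against an independent
Kaplan–Meier implementation on single-cause data).

## Standardization and effect measures

Pseudodata are row-wise bootstrap resamples of the empirical joint
baseline-confounder distribution (size 10,000 and 1,000 curve draws by
default; tests and the acceptance script scale these down — typically
300–500 pseudo-rows and 100–500 curve draws at n=800–2,000 subjects —
sizes chosen to keep Monte-Carlo error well inside the tolerances being
tested, as verified by the doubling-stability check). Subgroup
standardization conditions the resampling source instead of
marginalizing. When fewer curve draws than stored posterior draws are
requested, an evenly spaced subset is used so contrasts stay paired by
draw. RR is defined on standardized cumulative incidence; zero-incidence
denominators are reported as missing, never infinite, and T1 (incidence
identically 0) is always missing. Credible intervals are equal-tailed.
ARR is the posterior-mean incidence difference at the final wave by
default; NNT is the nearest integer to 1/ARR and not-applicable when
ARR ≤ 0.

## Imputation

Chained equations with a BART conditional model per incomplete variable
(continuous or probit by type), initialized from observed marginals, 5
cycles and m=5 imputations by default. Each model's features are the
other risk factors, age, sex, wave, and the subject's leave-one-out mean
of the target variable at other waves — in longitudinal data the
subject's own other waves dominate any cross-sectional predictor.
Observed cells are never altered. Downstream analyses run once per
completed dataset; posterior draws are pooled by simple mixing, since no
pooling rule is prescribed by the emulated analysis.

## Episodic-memory decline events

The decline rule is a declared operationalization (the emulated study's
exact rule is not public): residualize each composite against the mean
of same-age (±5 years) peers at the same wave, then call an event at the
first wave where the residual falls ≥1 pooled SD below the subject's own
baseline residual; otherwise censor at the last observation. Analysis is
restricted to entry ages ≤65. Events are monotone in the threshold by
construction. Event tables feed the same person-period → probit-BART →
standardization machinery as a two-state model.

## Problem sizes and runtime

The test suite and acceptance script use scaled-down study conditions
chosen to keep Monte-Carlo error small relative to each check's
tolerance: cohorts of 800–2,000 subjects, 20-tree forests with 100–200
burn-in and 200–500 retained draws, pseudodata of 300–500 rows. The full
suite runs in ≈5 minutes and the acceptance script in ≈1 minute on one
CPU. Null-calibration uses 20 replicates at n=800 with 100 standardized
curve draws per replicate.

## Known limitations

- Linear residualization under-corrects the multiplicative age/level
  dependence of risk growth (see trajectory section).
- The pattern-mixture estimator is unbiased only when every pattern's
  slopes are estimable (≥2 observed waves) and within-pattern slopes are
  representative; informative dropout *within* the first two waves is
  not correctable.
- Probit BART's pointwise null wiggle (above) makes pointwise hazard
  contrasts noisy at small n; standardized contrasts are the supported
  inference target.
- The EM-decline magnitudes depend strongly on the declared decline rule
  and the generator's slope-heterogeneity default; only directional and
  structural properties are asserted.
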