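# cvdtraj

Longitudinal cardiovascular-risk trajectories and their consequences for
dementia incidence and episodic-memory decline, analysed with Bayesian
additive regression trees (BART) as a discrete-time multistate survival
engine and Bayesian regression standardization for marginal effect
measures.

## Who this is for

Epidemiologists and biostatisticians who want to move beyond
cross-sectional risk scores: instead of asking *"what is your Framingham
risk today?"*, the pipeline asks *"how has your risk been changing over
decades, and what does that trajectory imply for your dementia risk?"*.
Because the motivating cohort data (5-year waves over 20–25 years,
entry ages 35–80) are access-restricted, the package ships a first-class
synthetic cohort generator that emulates the study's structure — wave
dropout that depends on latent outcomes, item-level missing risk factors,
multistate transitions concentrated in old age — so every stage is
testable end to end with known ground truth.

## The model

**Risk scoring.** The office-based (non-laboratory) Framingham general-CVD
function gives each subject a 10-year risk probability per wave:

    risk = 1 − S₀^exp(LP − mean(LP)),
    LP = β₁·ln(age) + β₂·ln(BMI) + β₃·ln(SBP) [treated/untreated]
       + β₄·smoker + β₅·diabetes            (sex-specific coefficients)

**Trajectory classes.** Per-subject OLS slopes of risk against time
(pre-diagnosis waves only, ≥2 values), residualized on baseline age and
baseline risk, are classified against pattern-mixture population moments
(stratified by dropout pattern, recombined by pattern frequency):
*accelerated* (> mean + 1 SD), *stable* (< mean − 1 SD), else *average*.

**Multistate hazards.** The illness-death model (healthy → dementia →
death, healthy → death; optionally with AD and VaD as separate states) is
decoupled into transition-specific discrete-time hazard models in
person-period format. Each transition gets a probit-BART fit with the
interval index as a free feature, so hazards are time-varying and
non-proportional. The BART sampler (sum of trees, regularization prior
α(1+d)^−β, grow/prune/change Metropolis–Hastings, conjugate leaf and
variance updates, probit latent augmentation) is implemented in this
package and validated against exact posterior enumeration on small tree
spaces.

**Standardization (g-computation).** For each posterior draw, baseline
confounders (age, sex, education, APOE ε4) are resampled as pseudodata,
the exposure group is fixed, per-row occupation curves are composed by
forward recursion and averaged — one standardized incidence curve per
draw. Curves are contrasted into RR(t) with equal-tailed 95% credible
intervals, the absolute risk reduction (ARR) at a reference wave, and the
number needed to treat (NNT = nearest integer to 1/ARR).

## Worked example

Plant a 3× accelerated-class hazard on the dementia transitions in a
synthetic cohort of 2,000 and recover it as a standardized risk ratio:

```python
from cvdtraj import (GeneratorConfig, generate_cohort, expand_person_period,
                     fit_transitions, sample_pseudodata, standardized_curves,
                     risk_ratio, arr_nnt, ILLNESS_DEATH)
from cvdtraj.multistate import baseline_table, GROUP_CODES

cfg = GeneratorConfig(n_subjects=2000, seed=7)
for tr in ("healthy->AD", "healthy->VaD"):
    cfg.hazard_params[tr]["class"] = {"accelerated": 3.0, "average": 1.7, "stable": 1.0}
cohort, truth = generate_cohort(cfg)

groups = truth.set_index("subject_id")["true_class"]
tables = expand_person_period(cohort, ILLNESS_DEATH, groups=groups)
posteriors = fit_transitions(tables, n_trees=20, n_burn=150, n_draws=500, random_state=5)

baseline = baseline_table(cohort).drop(columns="subject_id")
pseudo = sample_pseudodata(baseline, 500, seed=2)
curves = {g: standardized_curves(posteriors, pseudo, g, GROUP_CODES, n_curve_draws=500)
          for g in ("accelerated", "stable")}
rr = risk_ratio(curves["accelerated"], curves["stable"])
```

Output (about one minute on one CPU):

```
T2: RR = 3.99  (95% CrI 2.52-5.91)
T3: RR = 3.62  (95% CrI 2.37-5.21)
T4: RR = 3.10  (95% CrI 2.32-4.14)
T5: RR = 2.98  (95% CrI 2.27-3.85)
T6: RR = 2.72  (95% CrI 2.13-3.43)
ARR (stable vs accelerated, T6) = 20.9%  ->  NNT = 5
```

The posterior-mean RR is largest early and declines over follow-up —
the characteristic shape when an exposure advances event times — and the
credible intervals exclude 1 at every wave, recovering the planted
effect. The ARR is the difference in standardized cumulative incidence
at the final wave; its reciprocal is the NNT.

The same machinery runs from the shell:

```bash
cvdtraj all --out run1 --seed 1 --n-subjects 1200
```

which writes the cohort, ground truth, trajectory labels, per-transition
posteriors, RR tables, ARR/NNT summaries, and per-group descriptive
tables, each with a manifest for reproducibility.

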