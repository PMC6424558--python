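# Methods

`gestage` implements and validates postnatal gestational-age (GA) dating
from newborn dried-blood-spot metabolic profiles. Because record-level
newborn-screening data are never publicly deposited, the package pairs the
analysis with a cohort simulator whose marginal and conditional structure
matches what such studies report, so every stage — screening, multiple
imputation, model fitting, pooled scoring, and validation reporting — is
exercised end to end without any external data.

## The prediction models

GA in weeks is regressed on sample-level predictors in a three-model
hierarchy:

* **Model 1 (baseline)** — infant sex, multiple-birth status, birthweight.
* **Model 2 (analyte)** — sex, multiple birth, the analyte panel, and
  pairwise analyte interactions; birthweight excluded.
* **Model 3 (full)** — all clinical covariates plus analytes and
  interactions.

Fitting is elastic-net penalized least squares, mixing parameter
`l1_ratio = 0.5`, over a geometric penalty grid (80 values, down to 1e-5
of the data-derived maximum), with 10-fold cross-validation choosing the
penalty at minimum CV error. The intercept is unpenalized. Continuous
predictors are standardized to zero mean, unit SD on the training set;
interactions are products of standardized main effects, themselves
standardized; binary indicators (sex: female = 0 / male = 1; multiple
birth: no = 0 / yes = 1) are left as 0/1. Column order is deterministic
(clinical, analytes alphabetical, pairs lexicographic), zero-variance
columns are dropped with a warning, and fits are reproducible given the
fold-shuffle seed.

Interaction scope defaults to all pairs among the seven analytes with the
strongest independent GA contribution in this class of models — the
fetal/adult hemoglobin ratio, TSH, 17-OHP, alanine, C5, C4DC and tyrosine
— because unrestricted all-pairs interactions over a 47-analyte panel add
~1000 columns for no measurable gain on the simulated cohorts; `"all"`
remains available. Heel-prick and cord cohorts are fitted separately (no
sample-type covariate): their analyte distributions differ systematically
through collection timing, and validation studies report them separately.
No nonlinear basis terms are used. A log1p transform of analyte main
effects is exposed (`log_transform`) but off by default. Predictions are
unclipped by default; an optional clip range exists for deployment-style
use.

## Cohort simulator

One row per sample; an infant contributes a heel sample, a cord sample,
or both (default 42.5% paired, 3.1% heel-only, the rest cord-only; paired
rows share all clinical covariates).

* **GA (weeks)** — two-component mixture: a preterm tail, truncated
  normal on [24, 37) with mean 34.8 and SD 1.9 wk (fixed; it puts ~0.3%
  of births below 32 wk), and a term component, truncated normal on
  [37, 43], whose location and spread are solved numerically so the
  mixture attains the configured overall mean (39.1 wk), SD (1.5 wk) and
  preterm fraction (7%). This reproduces the left-skewed, term-dominated
  shape of facility-birth cohorts. Configurations whose preterm tail
  alone exceeds the requested overall variance are rejected as infeasible.
* **Birthweight (g)** — conditional on GA and sex:
  `bw = term_mean + b·(ga − m_term) + 60·(male − ½) + ε`, with the slope
  `b` derived from the configured term/preterm means and the mixture
  component locations (~125 g/wk at defaults), and `ε` Gaussian with SD
  chosen so the term-infant SD matches its configured value (~385 g).
  Clipped to [300, 6000] g.
* **Collection age (h)** — truncated normals: heel 15.0 ± 6.5 h on
  [0.4, 72]; cord 0.06 ± 0.25 h on [0, 2.017].
* **Analytes** — each value is
  `intercept + ga_slope·(ga − 40) + age_slope·age + cord_shift·1{cord} + noise`,
  truncated at zero (concentrations are nonnegative). Noise is decomposed
  into an analyte-specific part and a latent factor shared within analyte
  group (amino acids, acylcarnitines, endocrine, hemoglobin, other) with
  weight `correlation_strength` (default 0.3), preserving each marginal
  SD while inducing the cross-analyte correlation that makes chained
  imputation non-trivial.

The seven signal-bearing analytes have GA slopes of the physiologically
expected sign (hemoglobin ratio and TSH fall with GA; TSH rises steeply
over the first postnatal day, so heel and cord TSH means differ). Their
noise SDs are **calibration constants, not assay values**: they were fixed
once so that a refit Model 3 attains heel RMSE ≈ 1.0 wk at n = 5000
(giving Models 1/2/3 ≈ 1.42/1.06/0.99 wk externally), preserving the
qualitative hierarchy that full > analyte > baseline. The remaining 40
analytes carry no GA signal and act as selection noise for the penalty.

**Missingness** is MCAR per cell (default rate 0.13%, giving ~5–6% of
samples at least one missing analyte), capped at 5 of 47 per sample by
random-priority thinning; a MAR option doubles the rate for cord samples.
A fully-missing sample can be injected to exercise screening.

What the simulator does **not** emulate: assay/plate effects, skewed or
heavy-tailed analyte distributions, nonlinear analyte–GA relationships,
ethnicity- or feeding-related shifts, twin-pair correlation, and — most
importantly — development-to-validation population shift. Consequently the
external RMSEs here are closer to in-distribution error than a real
cross-country validation would be, and passing tests demonstrate the
correctness of the machinery, not field performance.

## Screening, imputation, pooling

Samples whose missing-analyte fraction is ≥ the exclusion threshold
(default 1.0, i.e. only 100%-missing samples) are excluded with reason
codes; all others are retained, flagged for imputation when ≥ 1 analyte is
missing. Missing analytes are multiply imputed (default m = 10) by
chained-equations regression with posterior draws (Bayesian ridge per
analyte), conditioning on all observed analytes plus sex, multiple birth,
birthweight and sample type. GA is deliberately **excluded** from the
imputation model because it is the prediction target; conditioning on it
would leak outcome information into the predictors. Observed cells are
restored exactly after imputation. Copies use seed-derived independent
streams, so the whole set is reproducible.

Every downstream quantity is computed per completed copy and pooled:
scalars (predictions, RMSE, AUC, CI bounds) by the arithmetic mean;
counts by the mean rounded to the closest integer with ties rounded half
away from zero. Rubin's-rules variance combination is out of scope — only
pooled point metrics are reported.

## Reference charts and SGA

SGA10/SGA3 flag birthweights strictly below the 10th/3rd percentile for
(sex, completed GA week — floor binning). The default chart is a Gaussian
location/scale family per sex over weeks 24–43, matched to the simulator's
conditional birthweight model; the CSV chart format (`sex, ga_week,
location_g, scale_g, p03_g, p10_g, p50_g, p90_g`) accepts any real
population reference. Strict inequality at the percentile means a
birthweight exactly at P10 is not SGA. LMS/Box-Cox skew modelling is not
implemented.

## Validation surfaces

* **RMSE** — root mean square of (predicted − observed), in weeks.
* **Within-±k accuracy** — |residual| ≤ k (closed interval; a residual of
  exactly k counts as within), percent to one decimal, counts pooled
  across imputations by the closest-integer rule.
* **Residual diagnostics** — per-sample (observed GA, residual) rows plus
  mean residual per GA category (<37, 37–42, >42 wk).
* **Preterm discrimination** — positive class is preterm (observed GA
  < 37.0 wk), score is the negated pooled GA prediction. AUC is the
  midrank Mann–Whitney probability (ties count one half), identical to
  the trapezoidal area under the empirical curve; 95% CI by the DeLong
  variance estimator (default) or a stratified bootstrap (2000 reps,
  seeded). Under multiple imputation, AUC and CI bounds are averaged
  across copies. Single-class strata raise "AUC undefined"; empty strata
  report n = 0 with NaN metrics.
* **Calibration** — OLS of observed on predicted GA; adjusted prediction
  = intercept + slope·prediction. Predictions shrunken toward the cohort
  mean give slope > 1; the adjustment is optional in the pipeline.

Reporting precision follows the field's convention: percentages to one
decimal, RMSE to two, AUC to three (one historical figure gloss equates
RMSE with average absolute deviation; the standard root-mean-square
definition is implemented).

## Pipeline and reproducibility

`run_pipeline` executes simulate (training) → simulate (external, with
missingness) → screen → impute → fit (per sample type × model) → score →
validate, writing cohorts, fitted models (JSON with spec, standardization
and coefficients; reload changes no prediction by more than 1e-12 wk),
estimate tables, and the accuracy/AUC/residual reports, plus a manifest
with per-stage status and seeds. A single master seed is fanned out as
`SeedSequence([master, stage_index])`, so stages are isolated but the run
is byte-identical under a fixed seed.

Default problem sizes — training n = 5000 infants, external n ≈ 1069
infants (~487 heel, ~1036 cord samples), m = 10 imputations — were chosen
to be large enough for stable RMSE/AUC estimates while keeping a full run
under a minute on one CPU; the test suite uses smaller cohorts (200–5000)
per check.

## Known limitations

* The elastic-net hierarchy is refit on simulated development data; the
  coefficients of any real deployed model are not reproduced here.
* Exact published validation metrics from real cohorts reflect population
  shift between development and validation settings that the simulator
  does not model; only the qualitative structure (model ordering,
  residual patterns, SGA behaviour) transfers.
* The default 47-analyte panel is a plausible stand-in; real screening
  panels differ by jurisdiction and the panel is fully configurable.
* DeLong CIs are asymptotic and degrade below ~20 positives; the bootstrap
  option is preferable for very preterm-sparse strata.
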