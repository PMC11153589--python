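# Methods

This note documents the models and procedures the package implements, the
defaults it ships, the choices that were genuinely open, and what the
synthetic experiments do and do not demonstrate.

## Synthetic cohorts

Patient-level CLL EHR data cannot be shared, so every experiment runs on
simulated cohorts. The generator emulates the *structure* that matters to the
pipeline, not clinical realism per se.

**Baseline covariates.** Categorical markers are drawn independently per
patient from preset prevalences: Binet stage, IGHV mutational status,
β2-microglobulin dichotomized at 4 mg/L, FISH hierarchy, ECOG performance
status, sex, and age dichotomized at 65 years. The `research` preset uses
Binet A/B/C = 85.4/11.9/2.7%, IGHV unmutated 29.7%, β2M > 4 12.0%, P(age ≥ 65)
= 0.701; the `deployment` preset uses 88.1/6.5/5.4%, 29.8%, 15.2% and 0.764.
FISH and ECOG distributions are not published for these cohorts; the shipped
values (del13q 40%, normal 25%, trisomy-12 15%, del11q 12%, del17p 8%; ECOG
0/1/2+ = 60/30/10%) are typical of newly diagnosed CLL and configurable.

**Outcome model.** Two cause-specific exponential clocks (severe infection,
CLL treatment) start at the prediction point; the first to fire sets the
composite event and its type. Each patient's total hazard is
`(h_inf + h_trt) · exp(lp)` with a log-linear predictor over baseline
covariates. Coefficients default to published CLL prognostic effect sizes
(log hazard ratios: IGHV unmutated 0.96, Binet B 0.55, Binet C 1.10,
β2M > 4 0.70, del17p 1.40, age ≥ 65 0.53, ECOG 2+ 0.50). When a preset
specifies a target 2-year composite rate (33% research, 40.6% deployment),
both baseline hazards are rescaled by a common factor solved on the drawn
cohort so the expected rate matches the target exactly; the infection /
treatment split follows the ratio of the baseline hazards (deployment
23.2 : 17.5). This is the simplest competing-risks generator with tunable
rates; proportionality over time is assumed and no treatment-line dynamics
are modelled. Administrative censoring is uniform on 1–6 years from
diagnosis, so a realistic share of patients has follow-up shorter than the
2-year horizon and exercises the exclusion rule.

**Event streams.** Laboratory values are stationary i.i.d. log-normal series
(no autocorrelation, no trends — deliberately uninformative about outcome) at
4 tests/patient-year over a per-patient history window: uniform 8–12 years
pre-prediction-point in `research`, 0.3–1.5 years in `deployment`, extending
forward to end of follow-up so leakage protection is actually exercised.
Blood cultures are a Poisson stream (0.3 events/patient-year) with history
capped at 10 vs 1 year. The default panel has 33 laboratory variables.

**Missingness.** Injected MCAR per variable *after* outcomes are drawn:
baseline values become the explicit `unknown` category, laboratory variables
are dropped wholesale per patient. Deployment preset: Binet 72.2%, IGHV
91.1%, β2M 35.8%, FISH 99.5%, ECOG 100%; research: 0/21.1/23.6/0/0.4%.
Because injection is independent across variables, the joint availability of
the five comparator inputs is the product of the marginals — near zero under
the deployment profile — whereas in real EHRs missingness is correlated
(structured-entry practice differs by site), which is why the real
complete-case coverage (0.63%) is low but nonzero. The qualitative collapse
is reproduced; the exact figure is not a target of the simulation.

**What passing tests show.** That the pipeline's contracts hold (calibrated
rates, no leakage, full coverage, bit-identical harmonization, monitoring
size/power) on data with the stated structure. They do not show clinical
performance on real cohorts: the synthetic labs carry no signal, so all
discrimination flows through the baseline markers and the achievable MCC
(~0.35–0.4 at the generator's Bayes limit) is a property of the simulation,
not of any real model — reported clinical performance lives on data this
generator does not pretend to replicate.

## Features

Time conventions are fixed in integer days: 3 months = 92, 2 years = 730,
7 years = 2557; windows are closed intervals `[t₀ − W, t₀]`. Aggregators:
min, max, median, mean, latest, count, days-since-latest. Counts are 0 on
empty windows (absence is information); value aggregators and
days-since-latest are NaN. Tied timestamps aggregate over all tied values.
Baseline variables are one-hot with an explicit `unknown` level so exactly
one indicator is 1 per variable. The default registry (per lab:
{min, median, count, days-since-latest} × {90 d, 2557 d}; cultures:
{count, days-since-latest} × {365 d, 2557 d}; plus the one-hots)
*approximates* the production model's 228-feature design at configurable
scale; the exact selected feature list is an output of its original
development pipeline and can be supplied as an explicit registry if
available.

## Ensemble

Default composition 13/7/4/2/2 (boosted trees / RF / extra trees /
elastic-net / logistic), outcome split 20 composite / 5 treatment / 3
infection, with the outcome-specific learners interleaved across families.
Feature bags are sampled without replacement per learner seed;
`bag_fraction` defaults to 0.5. Missing policy follows the family: boosted
trees receive NaN natively; all others median-impute with medians fitted on
training data only; linear families additionally standardize.

Hyperparameter defaults: boosted trees 100 rounds, depth 3, learning rate
0.2; forest families 200 trees with `min_samples_leaf=15`, `max_features=0.3`
and no depth cap — leaf-size regularization was chosen over a hard depth cap
because depth-limited forests collapsed the vote's spread on cohorts of a
few hundred patients (the single best forest then reaches the generator's
oracle AUC); elastic-net mixing 0.5. All overridable per family via
`EnsembleConfig.hyperparameters`.

**Confidence and thresholds.** The soft vote averages *all* learners
equally, outcome-specific ones included — their lower-prevalence targets
legitimately pull the composite mean down, which is part of the design's
robustness story. The packaged cutoffs (t_high, t_low) = (0.58, 0.28) are
the original deployment's values and are kept as defaults; on synthetic
cohorts the benchmarking utilities re-derive cutoffs with the same 20%/30%
upper/lower-quantile rule those values came from, because a fixed cutoff is
only meaningful relative to the confidence distribution it was derived on.
Mid-band patients are dichotomized at 0.5 for "all predictions" analyses (an
open choice; the band machinery itself never needs it). Raising t_high
(e.g. 0.58 → 0.65) can only shrink the high-confidence high-risk group.

**Risk factors.** Per-feature contributions are computed by occlusion to the
missing representation: contribution(f) = c(x) − c(x with f set to 0 for
count/indicator features, NaN otherwise). This reuses the missingness
machinery, is model-agnostic, and is exactly zero for features no learner's
bag uses. Top-5 positive and negative contributions are reported, ties
broken by feature id. Occlusion attributions are not Shapley values: they
measure one-feature-at-a-time deviations from the observed row.

## Evaluation

Positive = composite first event within 730 days of t₀; negative =
event-free with follow-up ≥ 730 days (events beyond the horizon are
negatives for classification but keep their event time for survival);
excluded = event-free follow-up < 730 days, retained right-censored for
Kaplan–Meier/Cox. MCC, precision, recall from the standard formulas with
explicit `None` on zero denominators; PR-AUC is the step-wise
non-interpolated area (constant scores degenerate to prevalence, by
convention). Bootstrap CIs are percentile, 5000 replicates by default,
resampling patients with replacement within predicted-risk strata so every
replicate preserves the high/low-risk ratio; the CI method behind the
original benchmark tables is not stated, and percentile was chosen for
simplicity. The comparator is the five-variable CLL-IPI weighting (age>65: 1,
Binet B/C: 1, β2M>4: 2, IGHV unmutated: 2, del17p/TP53: 4; categories
0–1/2–3/4–5/6–10), complete-case by default, with an optional mode imputing
Binet and IGHV to their favourable modes.

## Harmonization

Two many-to-one dictionaries (source label → canonical name;
(variable, source unit) → linear factor+offset) canonicalize raw tables;
uncovered rows are reported, never silently dropped. Validation matches the
model's three outputs per patient across sources: risk call, confidence
(default tolerance 0 = bit-identical) and the ordered top-5 up/down factor
lists. Bit-identity through a unit conversion holds exactly when the
round-trip `(v/f)·f` is exact in binary floating point (e.g. power-of-two
factors, as in the shipped fixtures); for arbitrary factors the conversion
can differ in the last ulp and a small tolerance flag exists. Localization
implicates features whose contributions differ beyond tolerance, maps them
to variables through the registry, and ranks variables whose own feature
values differ across sources first — nonlinear learners spread contribution
discrepancies onto clean variables, and inspecting the raw inputs behind
implicated features (as the manual workflow does) separates the true
offender. The harmonize → match → localize loop treats dictionary edits as
external human input between iterations and stops on perfect match or an
iteration cap. Nonlinear unit conversions are out of scope.

## Monitoring

Windows default to 91 days (quarterly); a remainder shorter than one window
folds into the final window, flagged partial. Numeric inputs are compared to
a reference snapshot by PSI over reference deciles (0.5 pseudo-count per bin
keeps it finite; zero iff the binned distributions coincide) and a
two-sample KS test; categorical inputs and the confidence distribution by
PSI over categories. Flags: PSI > 0.2 (the conventional "significant shift"
cut) or KS below a Bonferroni-split family alpha of 0.01. Performance (MCC,
precision, recall) is computed only on patients whose 2-year horizon has
matured inside the window and compared to reference performance with a
0.15 absolute drop margin. The alarm is a pure function of
(reference, current, config). Measured on the shipped defaults: family-wise
false-alarm 0.5% over 200 null windows; a 2-SD mean shift in one variable at
n = 1000/window is flagged in 100/100 seeds. Retraining and rollback are out
of scope.

## Problem sizes

The test suite and the acceptance script use cohorts of 15–5000 patients: a
6-lab panel (75 features) for harmonization fixtures and unit tests, the
full 33-lab panel (282 features) for pipeline-scale runs; ensembles of 5–7
learners for fixtures and the full 28 for pipeline runs; 10 train/test seed
pairs for the confidence-direction check; 100–200 seeds for the monitoring
and Cox-recovery simulations; 2000–5000 bootstrap replicates. These sizes
were chosen so the distributional claims under test are resolvable at their
stated tolerances.

## Known limitations

- Laboratory dynamics are exchangeable noise; no autocorrelation, trends or
  treatment effects, so temporal-feature importance cannot be studied.
- Missingness is MCAR and independent across variables; informative or
  correlated missingness (the realistic case) is only reachable by
  constructing custom profiles.
- The registry approximates, not replicates, the production feature set, and
  trained synthetic models share no parameters with the deployed model.
- Calendar structure is flattened to integer day offsets; no seasonality.
- The harmonization bit-identity contract needs exactly representable unit
  conversions; real conversions require the tolerance flag.
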