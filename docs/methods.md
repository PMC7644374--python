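# Methods

`fairmort` implements a fairness-audited pipeline for in-hospital
mortality prediction in the ICU: a synthetic cohort generator, cohort
preparation, rules-based severity-score comparators with monotone
empirical calibration, demographic-prevalence-ratio reweighting within
age strata, gradient-boosted risk modelling under stratified 10-fold
cross-validation, and a bias audit built on the equal opportunity
difference (EOD). This note records the models, the parameters that
matter, the numerical conventions, and the design decisions taken where
the design was genuinely open.

## The synthetic cohort

Real critical-care extracts of this kind are credential-gated, so the
package ships a generator that emulates the statistical structure the
analysis needs rather than any particular dataset. Each encounter has:

* **Race group.** Nonwhite with probability `nonwhite_prevalence`
  (default 0.18). A configurable fraction (default 2%) of encounters
  carries an absent or uninformative race string ("", "unknown",
  "declined to state") to exercise the exclusion rule.
* **Age.** Normal per group (defaults: white mean 62, nonwhite mean 57,
  SD 17 years), truncated to [18, 95]. Nonwhite patients are younger on
  average, which makes age a weak race proxy and creates the age–race
  confounding the stratified reweighting is designed for.
* **Latent severity.** A scalar `z ~ N(0, severity_sd)` plus
  `severity_shift_nonwhite` (default +0.5 SD) for nonwhite encounters.
* **Outcome.** In-hospital death drawn from
  `logit p = -1.1 + 0.6 * (age - 60)/17 + 1.4 * z + bias_strength * 1[nonwhite]`,
  giving an overall mortality near 30%. `bias_strength` (log-odds,
  default 0) is the race-linked outcome dependence *not* mediated by
  severity or measurements — the quantity the reweighting preprocessing
  is meant to neutralize.
* **Measurements.** Hourly values of 13 variables over `window_hours`:
  baseline physiological norms, a severity-proportional derangement in
  the clinically worse direction, a per-encounter offset, and AR(1)
  hour-to-hour noise (rho = 0.7), clipped to physiological bounds. GCS
  is integer in [3, 15]; FiO2 is floor-bounded at 0.21. Each
  (variable, hour) cell is dropped with probability `missing_rate`
  (default 0.2) and duplicated within the hour with probability 0.15.
* **Race-linked measurement offsets.** By default nonwhite encounters
  have SpO2 readings +1.5 points and baseline creatinine +0.3 mg/dL
  (`group_offsets`). These emulate documented race-linked measurement
  and laboratory differences (pulse-oximetry overestimation of oxygen
  saturation, creatinine baselines entangled with race corrections).
* **Chronic flags.** Independent Bernoulli per condition with
  configurable prevalences; they exist to make the SAPS II / APACHE II
  chronic-health points exercisable.

### Why the generator gives the model a handle on race

A reweighting intervention can only change a model's behaviour if the
features carry information about group membership. If race were
statistically invisible in the features, the reweighted and unweighted
fits would coincide up to noise and no training-side intervention could
move the EOD. The generator therefore encodes race in the features
through three realistic channels: the age gap, the admission-severity
shift (later presentation), and the measurement offsets. Under this
structure, a model fitted to raw data learns a race-proxy risk uplift
that misallocates false negatives between groups; reweighting removes
the race–outcome dependence within age strata and centers the EOD. The
`CohortConfig.exchangeable` constructor switches all three channels off
(equal age means, zero shift, zero offsets, zero bias), producing the
group-exchangeable null condition used to check that the audit is
calibrated around 0.

The generator is illustrative, not calibrated to any real cohort: its
vitals are conditionally independent given severity, comorbidity is
independent of physiology, and mortality follows a single-index
logistic model. Passing tests therefore demonstrate the *internal*
correctness and the qualitative mechanism of the pipeline, not
performance to be expected on real ICU data.

## Cohort preparation

* **Inclusion.** An encounter is analysed iff its measurement stream
  spans at least `min_hours` (default 10) distinct hours after ICU
  admission, every one of the 13 variables appears at least once, and
  the race string is present and informative. Exclusions are attributed
  to the first failing criterion in that order.
* **Hourly binning.** Half-open intervals [h, h+1) from admission;
  multiple values of one variable within an hour are averaged. An event
  timestamped before admission raises (it signals an extraction bug).
* **Outlier nulling.** Per variable, values strictly above the
  cohort-wide 99th or strictly below the 1st percentile become missing.
  Percentiles use linear interpolation between order statistics and are
  computed once on the full prepared cohort, treating outlier deletion
  as data cleaning prior to modelling; per-training-fold thresholds can
  be had by passing precomputed `thresholds` per fold. Re-application
  with the same thresholds is a no-op.
* **Features.** One column per (variable, hour) pair plus age —
  13 x window + 1 columns (131 for the 10-hour window). Missingness is
  passed through; the learner must accept it natively. No imputation,
  by design.
* **Observation window.** `window_hours` is a parameter (default 24;
  the studies below use 10). Both the 10-hour and 24-hour layouts are
  supported because either is a defensible reading of hourly-data
  collection versus prediction-time conventions in this literature;
  neither is asserted as canonical.

## Severity scores

MEWS, SAPS II and APACHE II are implemented as band tables in versioned
CSV rule data (`fairmort/rules/`), one row per band with explicit edge
inclusivity. All bands are authored half-open `[lower, upper)`, which
pins the behaviour of continuous values at the integer edges of the
published tables (e.g. an SBP of 70.5 falls in the "<= 70" band's
half-open extension `(-inf, 71)`). Conventions:

* **Missing adds zero.** Any component missing from a snapshot
  contributes 0 points and is counted in `n_missing_components`.
* **Computable subsets.** Only components derivable from the 13
  captured variables, age, and chronic flags are scored. SAPS II omits
  urine output, bilirubin, bicarbonate, oxygenation and admission type;
  APACHE II omits arterial pH and hematocrit. APACHE II oxygenation
  uses an SpO2 proxy band table (>= 96% -> 0, 91–95 -> 1, 86–90 -> 3,
  < 86 -> 4), since PaO2 is not captured; MAP is (SBP + 2 DBP)/3.
* **"APACHE" means APACHE II**, the standard tabular variant computable
  from this variable set.
* **GCS.** Rounded to the nearest integer before scoring (hourly
  averaging of within-hour duplicates can produce fractional values).
  The MEWS consciousness component maps GCS to AVPU as 15 -> Alert (0),
  13–14 -> Voice (1), 9–12 -> Pain (2), <= 8 -> Unresponsive (3).
* **Chronic health.** SAPS II takes the worst applicable of metastatic
  cancer (9), hematologic malignancy (10), AIDS (17). APACHE II adds 5
  points for any severe organ insufficiency / immunocompromise flag,
  treating all ICU admissions as nonoperative (admission type is not
  captured).
* **Worst-in-window extraction.** For each variable, the hourly value
  that maximizes that variable's component points under the given score
  is selected (ties -> earliest hour); for APACHE II's MAP the SBP/DBP
  pair of the worst-MAP hour is carried. This makes each comparator a
  worst-in-window score, the usual convention for these instruments.

### Calibration of scores to probabilities

Each comparator score is mapped to the death fraction among training
encounters with that score; scanning scores in increasing order, any
probability below the running maximum is raised to it (carry-forward),
and unobserved intermediate scores inherit the running maximum, so the
map is total and monotone over the training range. Queries outside the
range clamp to the endpoint probabilities. Calibration is refit on the
training portion of every cross-validation fold. At small cohort sizes
the carry-forward rule is vulnerable to saturation (a death at a rare
low score propagates a high probability upward); this is inherent to
the rule and visible in smoke-scale runs, and it fades at the study
scale of several thousand encounters.

## Reweighting

Training examples are stratified by age (<18, 18–29, 30–39, 40–49,
50–59, 60–69, >= 70; completed years at admission, integer truncation)
and each (stratum s, group g, outcome y) cell is weighted by the
demographic prevalence ratio

    w(s, g, y) = (N_sg * N_sy) / (N_s * N_sgy),

the expected-under-independence cell probability over the observed one.
Within any stratum whose four cells are populated, the weighted joint
distribution of (group, outcome) factorizes exactly, the weighted death
rate is identical across groups (to machine precision), and the
weighted mass equals the raw stratum count. When a stratum contains a
single group or a single outcome, the formula collapses to weight 1 —
neutrality without special-casing. Weights are computed on the training
portion of each fold only; test-fold labels are never touched.

## Risk model

The learner is consulted through a two-method contract (`fit` with
per-example weights, `predict_proba`) so alternatives can be swapped
in. Three families are provided: gradient-boosted trees (XGBoost, the
default — handles missing values and weights natively), scikit-learn's
histogram gradient boosting, and L2-regularized logistic regression
(which rejects missing values, exercising the capability-error path).

Default XGBoost hyperparameters: 60 rounds, depth 3, learning rate 0.2,
`min_child_weight` 1, no subsampling, histogram tree method, single
thread. Shallow trees and a moderate learning rate were chosen as a
sensible operating point for cohorts of a few thousand encounters with
~100–300 columns; depth and the leaf-weight cap are the knobs worth
grid-searching on other data. Per-fold weights are normalized to mean 1
before fitting, which makes predictions exactly invariant to rescaling
all weights by a positive constant (otherwise L2 leaf regularization
breaks scale-freeness).

Cross-validation uses outcome-stratified folds (k = 10 by default):
within each class, shuffled indices are dealt in contiguous blocks,
with each class's remainder starting where the previous class's ended,
so total fold sizes differ by at most one and per-fold case counts
differ by at most one. Every encounter receives exactly one out-of-fold
prediction.

## Fairness evaluation

* **Operating point.** The alert threshold is the candidate predicted
  value whose *training-fold* sensitivity is closest to the target
  (default 0.75), ties broken toward higher specificity, then applied
  unchanged to the test fold. Selecting on training data mirrors the
  calibration flow and avoids tuning on the evaluation fold; because
  boosted models fit their training folds closely, realized test
  sensitivity runs below the nominal target (threshold-transfer
  shrinkage), more so at small n.
* **EOD.** FNR(nonwhite) − FNR(white) at the operating point, per fold;
  the sign convention is fixed (positive = nonwhite deaths missed more
  often). Folds in which a group has no deaths contribute no EOD value.
  Significance is a two-sided one-sample Student t test of the per-fold
  EODs against 0, treating folds as independent samples; zero-variance
  samples are flagged degenerate (p = 1 if the common value is 0, else
  p = 0).
* **Per-fold averaging.** All reported metrics are arithmetic means
  over folds; pooled-prediction alternatives can be computed from the
  emitted predictions file.
* **McNemar.** Two systems are compared on pooled out-of-fold alert
  correctness at their respective operating points, via the discordant
  counts b and c: exact binomial when b + c < 25, chi-square with
  continuity correction otherwise.
* **DOR / LR.** LR+ = sens/(1 − spec), LR− = (1 − sens)/spec,
  DOR = LR+/LR−; zero denominators yield flagged non-finite results.
* **Feature importance.** Per group, mean |SHAP contribution| via the
  booster's tree-path attribution when available, permutation
  importance otherwise; groups under 10 rows are skipped; the summary
  is the Spearman correlation of the two groups' rankings.

## Study conditions and problem sizes

The package-level studies (`fairmort.experiments`) use cohorts of 5,000
encounters over a 10-hour window, 10-fold cross-validation, and 20
seeds; the biased condition sets `bias_strength = 0.8` (odds ratio
~2.2, a strong but plausible unexplained disparity). At this scale the
paired contrast — mean |EOD| of the reweighted model versus the
unweighted model, assessed by a one-sided sign test over seeds — is
well resolved in a few minutes on one CPU, and the null study (20
group-exchangeable cohorts) bounds the audit's center to a few
thousandths. These sizes are the package's desk-scale analogue of the
tens-of-thousands-of-encounters setting the method targets; absolute
EOD magnitudes scale with the injected dependence and should not be
read as estimates for any real cohort.

## Known limitations

* The generator's physiology is a single-index model; it cannot probe
  failure modes driven by rich comorbidity structure or by feature
  correlations with race beyond the three channels built in.
* The carry-forward calibration saturates at small n (above).
* Severity-score engines cover only the computable component subsets;
  totals are not comparable to full-instrument scores on real data.
* The reweighting targets within-stratum independence of race and
  outcome; it is not a general-purpose fairness guarantee, and only the
  false-negative-rate criterion is audited (demographic parity,
  equalized odds on both rates, and within-group calibration are out of
  scope, though the confusion-count partition makes them easy to add).
* The t test over folds treats fold metrics as independent, the common
  but approximate convention for cross-validated audits.
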