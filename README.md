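# fairmort

Fairness-audited in-hospital mortality prediction for ICU cohorts.

Early-warning and severity scores (MEWS, SAPS II, APACHE II) and
machine-learned risk models are used to triage critically ill patients,
but they can miss deaths at different rates across racial groups. This
package implements, as a tested and reusable pipeline, an analysis that
quantifies that bias and removes it at training time:

1. **Synthetic ICU cohorts** — encounters with hourly measurements of
   13 common variables (blood pressures, heart rate, temperature,
   respiratory rate, SpO2, WBC, platelets, creatinine, GCS, FiO2,
   potassium, sodium), realistic missingness and within-hour
   duplicates, and a configurable race-linked outcome dependence.
2. **Cohort preparation** — inclusion criteria (≥ 10 hours of data, all
   13 variables present, usable race data), hourly binning with
   averaging, 1st/99th-percentile outlier nulling, feature assembly.
3. **Severity-score engines** — rules-based MEWS / SAPS II / APACHE II
   from versioned band tables, worst-in-window extraction,
   missing-adds-zero convention, and monotone empirical calibration of
   scores to mortality probabilities (carry-forward of the running
   maximum death rate).
4. **Reweighting** — within age strata (< 18, 18–29, …, ≥ 70), each
   training example is weighted by the demographic prevalence ratio

       w(s, g, y) = P_expected(g, y | s) / P_observed(g, y | s)
                  = (N_sg · N_sy) / (N_s · N_sgy),

   which renders race g and outcome y statistically independent in the
   weighted training data (Kamiran–Calders reweighing).
5. **Risk model** — gradient-boosted trees (XGBoost) with per-example
   weights and native missing-value handling, under outcome-stratified
   10-fold cross-validation; the learner is a pluggable contract.
6. **Bias audit** — AUROC, sensitivity/specificity at an operating
   point targeting sensitivity 0.75, diagnostic odds ratio, LR±, the
   **equal opportunity difference**

       EOD = FNR(nonwhite) − FNR(white),   FNR = FN / (FN + TP),

   tested against 0 by a per-fold Student t test, McNemar paired
   comparisons between systems, and group-wise feature importance.

An unbiased alert system has EOD 0: it misses deaths at the same rate
in both groups. The pipeline's central, reproducible finding on its
synthetic cohorts is that training-data reweighting shrinks |EOD|
substantially without costing discrimination.

See `docs/methods.md` for the models, conventions and design decisions.

## Worked example

Write a study configuration:

```yaml
# study.yaml — 5,000 encounters, 10-hour window, race-linked
# outcome dependence of 0.8 log-odds
n_encounters: 5000
window_hours: 10
min_hours: 10
bias_strength: 0.8
seed: 11
```

and run the whole pipeline:

```sh
fairmort run-all --config study.yaml --out runs/study
```

This simulates the cohort, applies the inclusion criteria, bins and
cleans the measurements, computes the three comparator scores, trains
the reweighted and unweighted models under 10-fold CV, and writes all
artifacts (`encounters.csv`, `measurements.csv`, `features.csv`,
`weights.csv`, `scores.csv`, `predictions.csv`, `report.json`,
`manifest.json`). The printed per-system summaries (fold-averaged) for
this configuration are:

| system            | AUROC | EOD    | EOD p |
|-------------------|-------|--------|-------|
| model, reweighted | 0.790 | −0.040 | 0.10  |
| model, unweighted | 0.797 | −0.103 | <0.001 |
| MEWS              | 0.699 | −0.035 | 0.07  |
| SAPS II           | 0.636 | +0.032 | 0.09  |
| APACHE II         | 0.603 | −0.038 | 0.16  |

Read: the learned model discriminates mortality far better than any
rules-based comparator (AUROC 0.79 vs 0.60–0.70). Trained on raw data
it is significantly biased — its false negative rate differs between
race groups by 0.103 (here favouring nonwhite patients, because the
model over-uses the race-correlated signal in the features). The same
model trained on reweighted data cuts that gap to 0.040, no longer
distinguishable from 0 at alpha 0.05, at essentially unchanged AUROC.
Each run is fully deterministic: rerunning the same configuration
reproduces `report.json` byte for byte.

The stages are also available individually (`simulate`, `prepare`,
`score`, `reweight`, `train`, `evaluate`) and as a Python API:

```python
from fairmort import (CohortConfig, generate_cohort, audit_model,
                      make_folds, LearnerSpec)
from fairmort.pipeline import prepare_features

encounters, measurements = generate_cohort(
    CohortConfig(n_encounters=5000, window_hours=10, bias_strength=0.8, seed=11)
)
fm, grid, tally, removed = prepare_features(encounters, measurements,
                                            window_hours=10)
folds = make_folds(len(fm), 10, seed=0, stratify_by=fm.y.to_numpy())
audit = audit_model(fm, LearnerSpec(), folds, reweight=True)
print(audit.mean_auroc, audit.mean_eod, audit.eod_test.p)
```

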