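"""Performance and bias statistics for the mortality audit.

Covers discrimination (AUROC), operating-point metrics (sensitivity,
specificity, likelihood ratios, diagnostic odds ratio), the equal
opportunity difference — the difference in false negative rates between
the nonwhite and white groups, 0 in expectation for an unbiased
predictor — with a one-sample t test over cross-validation folds, the
McNemar paired comparison of two alert systems, and group-wise feature
importance.

Sign convention: EOD = FNR(nonwhite) - FNR(white). A positive value
means deaths among nonwhite patients are missed more often.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(cls, outcomes, alerts) -> "ConfusionCounts":
        y = np.asarray(outcomes).astype(bool)
        a = np.asarray(alerts).astype(bool)
        return cls(
            tp=int((y & a).sum()),
            fp=int((~y & a).sum()),
            tn=int((~y & ~a).sum()),
            fn=int((y & ~a).sum()),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def counts_by_group(outcomes, alerts, groups) -> dict[str, ConfusionCounts]:
    groups = np.asarray(groups)
    outcomes = np.asarray(outcomes)
    alerts = np.asarray(alerts)
    return {
        g: ConfusionCounts.from_predictions(outcomes[groups == g],
                                            alerts[groups == g])
        for g in np.unique(groups)
    }


def auroc(probabilities, outcomes) -> float:
    """Probability that a random death outranks a random survivor
    (ties counted half)."""
    y = np.asarray(outcomes)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC requires both outcome classes")
    return float(roc_auc_score(y, np.asarray(probabilities)))


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


def select_threshold_for_sensitivity(
    probabilities, outcomes, target: float = 0.75
) -> OperatingPoint:
    """Pick the probability threshold (alert iff p >= threshold) whose
    sensitivity is closest to ``target``; ties break toward higher
    specificity. Candidate thresholds are the distinct predicted values
    plus 1.0 (the no-alert extreme)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("threshold selection requires at least one positive")
    n_neg = len(y) - n_pos
    candidates = np.unique(np.concatenate([p, [1.0]]))
    best = None
    for t in candidates:
        alert = p >= t
        sens = (alert & y).sum() / n_pos
        spec = (~alert & ~y).sum() / n_neg if n_neg else 1.0
        key = (abs(sens - target), -spec, -t)
        if best is None or key < best[0]:
            best = (key, OperatingPoint(float(t), float(sens), float(spec)))
    return best[1]


@dataclass(frozen=True)
class PerformanceMetrics:
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    dor: float
    finite: bool


def likelihood_ratios(sensitivity: float, specificity: float):
    """(LR+, LR-, DOR) from a (sensitivity, specificity) pair; non-finite
    values arise when a denominator is zero."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lr_pos = np.divide(sensitivity, 1.0 - specificity)
        lr_neg = np.divide(1.0 - sensitivity, specificity)
        dor = np.divide(lr_pos, lr_neg)
    return float(lr_pos), float(lr_neg), float(dor)


def performance_metrics(counts: ConfusionCounts) -> PerformanceMetrics:
    """Sensitivity, specificity, LR+, LR-, DOR; a zero denominator yields
    a flagged non-finite result rather than a silent infinity."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("performance metrics require both classes present")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    lr_pos, lr_neg, dor = likelihood_ratios(sens, spec)
    finite = all(np.isfinite(v) for v in (lr_pos, lr_neg, dor))
    return PerformanceMetrics(sens, spec, lr_pos, lr_neg, dor, finite)


def false_negative_rate(counts: ConfusionCounts) -> float:
    if counts.tp + counts.fn == 0:
        raise ValueError("FNR undefined without positives")
    return counts.fn / (counts.fn + counts.tp)


def equal_opportunity_difference(
    counts_by_group: dict[str, ConfusionCounts],
    protected: str = "nonwhite",
    reference: str = "white",
) -> float:
    """FNR(protected) - FNR(reference)."""
    for g in (protected, reference):
        if g not in counts_by_group:
            raise ValueError(f"group {g!r} missing from confusion counts")
        c = counts_by_group[g]
        if c.tp + c.fn == 0:
            raise ValueError(f"group {g!r} has no positive outcomes")
    return false_negative_rate(counts_by_group[protected]) - false_negative_rate(
        counts_by_group[reference]
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool


def eod_t_test(per_fold_eods) -> TTestResult:
    """Two-sided one-sample Student t test of per-fold EODs against 0.

    A zero-variance sample is flagged: p = 1 when the common value is 0
    (the null holds exactly), p = 0 otherwise.
    """
    x = np.asarray(per_fold_eods, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError("t test requires at least two folds")
    if np.ptp(x) == 0.0:
        if x[0] == 0.0:
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        return TTestResult(t=float(np.inf * np.sign(x[0])), p=0.0, degenerate=True)
    t, p = sps.ttest_1samp(x, 0.0)
    return TTestResult(t=float(t), p=float(p), degenerate=False)


@dataclass(frozen=True)
class McNemarResult:
    statistic: float
    p: float
    b: int
    c: int
    exact: bool


def mcnemar_compare(correct_a, correct_b) -> McNemarResult:
    """McNemar test on the discordant counts b (A correct, B wrong) and
    c (A wrong, B correct): exact binomial when b + c < 25, chi-square
    with continuity correction otherwise."""
    a = np.asarray(correct_a).astype(bool)
    b_vec = np.asarray(correct_b).astype(bool)
    if len(a) != len(b_vec):
        raise ValueError("case vectors must be aligned")
    b = int((a & ~b_vec).sum())
    c = int((~a & b_vec).sum())
    if b + c == 0:
        return McNemarResult(statistic=0.0, p=1.0, b=0, c=0, exact=True)
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    exact = (b + c) < 25
    table = [[int((a & b_vec).sum()), b], [c, int((~a & ~b_vec).sum())]]
    res = sm_mcnemar(table, exact=exact, correction=True)
    return McNemarResult(
        statistic=float(res.statistic), p=float(res.pvalue), b=b, c=c, exact=exact
    )


@dataclass
class GroupImportance:
    per_group: dict[str, pd.Series]
    rank_correlation: float


def group_feature_importance(
    model, X: pd.DataFrame, groups, y=None, min_rows: int = 10
) -> GroupImportance:
    """Per-feature importance computed separately on each group's rows.

    Uses tree-path attribution (mean |SHAP contribution|) when the model
    exposes an XGBoost booster, permutation importance otherwise (which
    requires ``y``). Groups with fewer than ``min_rows`` rows are
    skipped with a warning. The summary is the Spearman correlation of
    the two groups' importance rankings.
    """
    groups = np.asarray(groups)
    per_group: dict[str, pd.Series] = {}
    for g in np.unique(groups):
        rows = X[groups == g]
        if len(rows) < min_rows:
            warnings.warn(f"group {g!r} has fewer than {min_rows} rows; skipped")
            continue
        if hasattr(model, "booster"):
            import xgboost as xgb

            contrib = model.booster.predict(
                xgb.DMatrix(rows.to_numpy(dtype=float)), pred_contribs=True
            )
            imp = np.abs(contrib[:, :-1]).mean(axis=0)  # drop bias column
        else:
            from sklearn.inspection import permutation_importance

            if y is None:
                raise ValueError("permutation importance requires outcomes y")
            y_g = np.asarray(y)[groups == g]
            r = permutation_importance(
                model._model, rows.to_numpy(dtype=float), y_g,
                n_repeats=5, random_state=0
            )
            imp = r.importances_mean
        per_group[g] = pd.Series(imp, index=X.columns).sort_values(ascending=False)

    if len(per_group) >= 2:
        names = list(per_group)
        common = per_group[names[0]].index
        rho = sps.spearmanr(
            per_group[names[0]].loc[common], per_group[names[1]].loc[common]
        ).statistic
    else:
        rho = float("nan")
    return GroupImportance(per_group=per_group, rank_correlation=float(rho))
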