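"""End-to-end orchestration: cohort -> features -> models/comparators ->
fairness report, with per-stage seeds derived from one root seed.

Operating points are always selected on training folds (threshold whose
training sensitivity is closest to the target) and applied unchanged to
the held-out fold, mirroring the comparator calibration flow. Per-fold
metrics are averaged arithmetically across folds; folds in which a race
group has no deaths contribute no EOD value (recorded as NaN).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort_prep, fairness_eval, severity_scores
from .cohort_prep import FeatureMatrix
from .risk_model import CVFolds, LearnerSpec, make_folds, train_predict_cv
from .synthetic_cohort import CohortConfig, generate_cohort


def derive_seed(root_seed: int, label: str) -> int:
    """Stable per-stage seed below 2**31, keyed by stage label."""
    digest = hashlib.sha256(f"{root_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _safe_eod(outcomes, alerts, groups) -> float:
    by_group = fairness_eval.counts_by_group(outcomes, alerts, groups)
    try:
        return fairness_eval.equal_opportunity_difference(by_group)
    except ValueError:
        return float("nan")


def _group_fnrs(outcomes, alerts, groups) -> dict[str, float]:
    out = {}
    for g, c in fairness_eval.counts_by_group(outcomes, alerts, groups).items():
        out[g] = (
            fairness_eval.false_negative_rate(c) if c.tp + c.fn else float("nan")
        )
    return out


@dataclass
class ModelAudit:
    """Per-fold and averaged performance plus the EOD test for one
    prediction system."""

    name: str
    per_fold: pd.DataFrame
    eod_test: fairness_eval.TTestResult
    correct: pd.Series  # pooled out-of-fold alert correctness per encounter
    predictions: pd.DataFrame

    @property
    def mean_auroc(self) -> float:
        return float(self.per_fold["auroc"].mean())

    @property
    def mean_eod(self) -> float:
        return float(np.nanmean(self.per_fold["eod"]))

    def summary(self) -> dict:
        pf = self.per_fold
        return {
            "auroc": self.mean_auroc,
            "sensitivity": float(pf["sensitivity"].mean()),
            "specificity": float(pf["specificity"].mean()),
            "eod": self.mean_eod,
            "eod_t": self.eod_test.t,
            "eod_p": self.eod_test.p,
            "fnr_white": float(np.nanmean(pf["fnr_white"])),
            "fnr_nonwhite": float(np.nanmean(pf["fnr_nonwhite"])),
        }


def _audit_probabilities(
    name: str,
    fm: FeatureMatrix,
    folds: CVFolds,
    fold_probs,  # callable fold -> (train_probs, test_probs)
    target_sensitivity: float,
) -> ModelAudit:
    y = fm.y.to_numpy()
    groups = fm.group.to_numpy()
    ids = fm.encounter_ids.to_numpy()
    rows, correct, pred_rows = [], [], []
    for f in range(folds.k):
        train, test = folds.train_test(f)
        p_train, p_test = fold_probs(f)
        op = fairness_eval.select_threshold_for_sensitivity(
            p_train, y[train], target_sensitivity
        )
        alerts = p_test >= op.threshold
        counts = fairness_eval.ConfusionCounts.from_predictions(y[test], alerts)
        perf = fairness_eval.performance_metrics(counts)
        fnrs = _group_fnrs(y[test], alerts, groups[test])
        rows.append(
            {
                "fold": f,
                "auroc": fairness_eval.auroc(p_test, y[test]),
                "threshold": op.threshold,
                "sensitivity": perf.sensitivity,
                "specificity": perf.specificity,
                "eod": _safe_eod(y[test], alerts, groups[test]),
                "fnr_white": fnrs.get("white", float("nan")),
                "fnr_nonwhite": fnrs.get("nonwhite", float("nan")),
            }
        )
        correct.append(
            pd.Series(alerts == y[test].astype(bool), index=ids[test])
        )
        pred_rows.append(
            pd.DataFrame(
                {
                    "encounter_id": ids[test],
                    "fold": f,
                    "probability": p_test,
                    "outcome": y[test],
                    "group": groups[test],
                }
            )
        )
    per_fold = pd.DataFrame(rows)
    valid_eods = per_fold["eod"].dropna().to_numpy()
    if len(valid_eods) >= 2:
        eod_test = fairness_eval.eod_t_test(valid_eods)
    else:  # too few folds with deaths in both groups to test
        eod_test = fairness_eval.TTestResult(
            t=float("nan"), p=float("nan"), degenerate=True
        )
    return ModelAudit(
        name=name,
        per_fold=per_fold,
        eod_test=eod_test,
        correct=pd.concat(correct).sort_index(),
        predictions=pd.concat(pred_rows, ignore_index=True),
    )


def audit_model(
    fm: FeatureMatrix,
    spec: LearnerSpec,
    folds: CVFolds,
    reweight: bool = True,
    target_sensitivity: float = 0.75,
    name: str | None = None,
) -> ModelAudit:
    """Cross-validated audit of the learned model (optionally reweighted)."""
    fp = train_predict_cv(fm, spec, folds, reweight=reweight)
    X = fm.X.to_numpy(dtype=float)
    test_probs = {
        f: fp.frame.loc[fp.frame["fold"] == f, "probability"].to_numpy()
        for f in range(folds.k)
    }

    def fold_probs(f):
        train, _ = folds.train_test(f)
        return fp.models[f].predict_proba(X[train]), test_probs[f]

    audit = _audit_probabilities(
        name or ("model_reweighted" if reweight else "model_unweighted"),
        fm, folds, fold_probs, target_sensitivity,
    )
    audit.models = fp.models
    return audit


def audit_comparator(
    scores: pd.Series,
    fm: FeatureMatrix,
    folds: CVFolds,
    target_sensitivity: float = 0.75,
    name: str | None = None,
) -> ModelAudit:
    """Cross-validated audit of a rules-based score: per fold, the score
    is calibrated to mortality probabilities on the training encounters
    (empirical rates with monotone carry-forward) and assessed on the
    held-out fold."""
    s = scores.loc[fm.encounter_ids].to_numpy()
    y = fm.y.to_numpy()

    def fold_probs(f):
        train, test = folds.train_test(f)
        cal = severity_scores.calibrate_scores(s[train], y[train])
        return cal(s[train]), cal(s[test])

    return _audit_probabilities(
        name or str(scores.name), fm, folds, fold_probs, target_sensitivity
    )


@dataclass
class RunConfig:
    """One pipeline run: cohort condition, window, folds, learner, scores."""

    n_encounters: int = 2000
    seed: int = 0
    window_hours: int = 24
    min_hours: int = 10
    k_folds: int = 10
    bias_strength: float = 0.0
    learner_family: str = "xgboost"
    learner_params: dict = field(default_factory=dict)
    scores: tuple[str, ...] = ("mews", "saps2", "apache2")
    target_sensitivity: float = 0.75
    reweight: bool = True
    include_unweighted: bool = True
    cohort_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scores" in data:
            data["scores"] = tuple(data["scores"])
        return cls(**data)

    def cohort_config(self) -> CohortConfig:
        kwargs = dict(
            n_encounters=self.n_encounters,
            window_hours=self.window_hours,
            bias_strength=self.bias_strength,
            seed=derive_seed(self.seed, "cohort"),
        )
        kwargs.update(self.cohort_overrides)
        return CohortConfig(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def prepare_features(
    encounters: pd.DataFrame,
    measurements: pd.DataFrame,
    window_hours: int,
    min_hours: int = 10,
):
    """Inclusion -> hourly binning -> outlier nulling -> feature matrix."""
    included, tally = cohort_prep.apply_inclusion_criteria(
        encounters, measurements, min_hours=min_hours
    )
    grid = cohort_prep.bin_hourly(
        measurements, encounters, window_hours, encounter_ids=included
    )
    grid, removed, thresholds = cohort_prep.remove_outliers(grid)
    fm = cohort_prep.build_features(
        grid, encounters[encounters["encounter_id"].isin(included)]
    )
    return fm, grid, tally, removed


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages, writing every artifact plus a manifest to
    ``out_dir``; returns the report dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    encounters, measurements = generate_cohort(config.cohort_config())
    encounters.to_csv(out / "encounters.csv", index=False)
    measurements.to_csv(out / "measurements.csv", index=False)

    fm, grid, tally, removed = prepare_features(
        encounters, measurements, config.window_hours, config.min_hours
    )
    cohort_prep.write_features(fm, out / "features.csv")

    from .fair_reweighting import compute_reweights, write_weights

    _, whole_cohort_weights = compute_reweights(
        fm.stratum.to_numpy(), fm.group.to_numpy(), fm.y.to_numpy()
    )
    write_weights(fm, whole_cohort_weights, out / "weights.csv")

    folds = make_folds(
        len(fm), config.k_folds, derive_seed(config.seed, "folds"),
        stratify_by=fm.y.to_numpy(),
    )
    spec = LearnerSpec(
        family=config.learner_family,
        params=config.learner_params,
        seed=derive_seed(config.seed, "learner"),
    )

    audits: dict[str, ModelAudit] = {}
    if config.reweight:
        audits["model_reweighted"] = audit_model(
            fm, spec, folds, reweight=True,
            target_sensitivity=config.target_sensitivity,
        )
    if config.include_unweighted or not config.reweight:
        audits["model_unweighted"] = audit_model(
            fm, spec, folds, reweight=False,
            target_sensitivity=config.target_sensitivity,
        )
    primary = "model_reweighted" if config.reweight else "model_unweighted"
    audits[primary].predictions.to_csv(out / "predictions.csv", index=False)

    score_frames = {}
    for score_name in config.scores:
        totals = severity_scores.score_encounters(
            grid, encounters, score_name
        )
        score_frames[score_name] = totals
        audits[score_name] = audit_comparator(
            totals, fm, folds, config.target_sensitivity, name=score_name
        )
    if score_frames:
        pd.DataFrame(score_frames).to_csv(out / "scores.csv")

    mcnemar = {}
    for score_name in config.scores:
        res = fairness_eval.mcnemar_compare(
            audits[primary].correct.to_numpy(),
            audits[score_name].correct.loc[audits[primary].correct.index].to_numpy(),
        )
        mcnemar[score_name] = {
            "statistic": res.statistic, "p": res.p, "b": res.b, "c": res.c,
            "exact": res.exact,
        }

    report = {
        "config_hash": config.config_hash(),
        "n_included": len(fm),
        "exclusions": tally,
        "outliers_removed": removed,
        "systems": {
            name: {
                "summary": audit.summary(),
                "per_fold": _round_floats(
                    audit.per_fold.to_dict(orient="records")
                ),
            }
            for name, audit in audits.items()
        },
        "mcnemar_vs_" + primary: mcnemar,
    }
    report = _round_floats(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    artifacts = sorted(
        p.name for p in out.iterdir() if p.name not in ("manifest.json",)
    )
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": {
            s: derive_seed(config.seed, s) for s in ("cohort", "folds", "learner")
        },
        "artifacts": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in artifacts
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(_round_floats(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
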