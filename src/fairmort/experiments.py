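"""Multi-seed studies of the bias audit on synthetic cohorts.

Two study designs:

* ``bias_mitigation_study`` — cohorts carrying a race-linked outcome
  dependence (positive ``bias_strength`` on top of the generator's
  default race-linked severity shift and measurement offsets). For each
  seed the same cohort is modelled twice, with and without reweighting,
  and the per-seed mean equal opportunity differences are compared by a
  paired sign test on |EOD|.
* ``null_calibration_study`` — group-exchangeable cohorts (equal age
  distributions, no shift, no offsets, no outcome dependence), on which
  the EOD of the group-blind model should be centered at 0.

Study problem sizes default to 5,000 encounters over a 10-hour window,
a scale at which the contrast is well resolved on a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binomtest

from .pipeline import derive_seed, prepare_features
from .risk_model import LearnerSpec, make_folds
from .synthetic_cohort import CohortConfig, generate_cohort

STUDY_BIAS_STRENGTH = 0.8
STUDY_N_ENCOUNTERS = 5000
STUDY_WINDOW_HOURS = 10


def _audit_seed(config: CohortConfig, k: int, spec: LearnerSpec,
                reweight_arms: tuple[bool, ...], target: float) -> dict[bool, float]:
    from .pipeline import audit_model

    encounters, measurements = generate_cohort(config)
    fm, _, _, _ = prepare_features(
        encounters, measurements, config.window_hours, min_hours=config.window_hours
    )
    folds = make_folds(
        len(fm), k, derive_seed(config.seed, "folds"), stratify_by=fm.y.to_numpy()
    )
    out = {}
    for rw in reweight_arms:
        audit = audit_model(fm, spec, folds, reweight=rw, target_sensitivity=target)
        out[rw] = audit.mean_eod
    return out


@dataclass
class BiasMitigationResult:
    eod_unweighted: np.ndarray  # per-seed mean EOD, no reweighting
    eod_reweighted: np.ndarray
    wins: int                   # seeds where |EOD| shrank under reweighting
    n_seeds: int
    sign_test_p: float          # one-sided binomial, H1: reweighting shrinks |EOD|

    @property
    def mean_abs_unweighted(self) -> float:
        return float(np.mean(np.abs(self.eod_unweighted)))

    @property
    def mean_abs_reweighted(self) -> float:
        return float(np.mean(np.abs(self.eod_reweighted)))


def bias_mitigation_study(
    n_seeds: int = 20,
    n_encounters: int = STUDY_N_ENCOUNTERS,
    bias_strength: float = STUDY_BIAS_STRENGTH,
    window_hours: int = STUDY_WINDOW_HOURS,
    base_seed: int = 0,
    k: int = 10,
    spec: LearnerSpec | None = None,
    target_sensitivity: float = 0.75,
) -> BiasMitigationResult:
    """Paired reweighted-vs-unweighted EOD contrast over ``n_seeds`` cohorts."""
    spec = spec or LearnerSpec()
    unw, rw = [], []
    for i in range(n_seeds):
        config = CohortConfig(
            n_encounters=n_encounters,
            bias_strength=bias_strength,
            window_hours=window_hours,
            seed=derive_seed(base_seed, f"bias-cohort-{i}"),
        )
        eods = _audit_seed(config, k, spec, (False, True), target_sensitivity)
        unw.append(eods[False])
        rw.append(eods[True])
    unw, rw = np.asarray(unw), np.asarray(rw)
    wins = int((np.abs(rw) < np.abs(unw)).sum())
    p = binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue
    return BiasMitigationResult(
        eod_unweighted=unw, eod_reweighted=rw, wins=wins, n_seeds=n_seeds,
        sign_test_p=float(p),
    )


@dataclass
class NullCalibrationResult:
    eods: np.ndarray
    mean: float
    se: float

    @property
    def centered_at_zero(self) -> bool:
        """|mean| within two standard errors of 0."""
        return abs(self.mean) <= 2.0 * self.se


def null_calibration_study(
    n_seeds: int = 20,
    n_encounters: int = STUDY_N_ENCOUNTERS,
    window_hours: int = STUDY_WINDOW_HOURS,
    base_seed: int = 0,
    k: int = 10,
    spec: LearnerSpec | None = None,
    target_sensitivity: float = 0.75,
) -> NullCalibrationResult:
    """EOD of the group-blind model on group-exchangeable cohorts."""
    spec = spec or LearnerSpec()
    eods = []
    for i in range(n_seeds):
        config = CohortConfig.exchangeable(
            n_encounters,
            seed=derive_seed(base_seed, f"null-cohort-{i}"),
            window_hours=window_hours,
        )
        eods.append(
            _audit_seed(config, k, spec, (False,), target_sensitivity)[False]
        )
    eods = np.asarray(eods)
    return NullCalibrationResult(
        eods=eods,
        mean=float(np.mean(eods)),
        se=float(np.std(eods, ddof=1) / np.sqrt(len(eods))),
    )
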