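"""Synthetic ICU cohort generator.

Emulates the statistical structure of an adult ICU extract from an
electronic health record: ~18% nonwhite prevalence, nonwhite patients
younger on average, hourly measurements of 13 common variables with
within-hour duplicates and missingness, and a latent admission severity
that drives both vitals derangement and in-hospital mortality.

Two race-linked mechanisms beyond age are generated by default, because
they are what gives a race-blind risk model any handle on group
membership and hence gives reweighting something to act on:

* nonwhite encounters carry a higher mean admission severity
  (``severity_shift_nonwhite``), emulating later presentation;
* two variables carry additive race-linked measurement offsets
  (``group_offsets``; by default SpO2 reads higher and baseline
  creatinine is higher for nonwhite patients), emulating documented
  device and laboratory biases.

On top of that, ``bias_strength`` adds a race-linked log-odds increment
to mortality that is *not* mediated by severity or vitals — the
dependence the reweighting preprocessing is meant to neutralize.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .variables import AR1_RHO, MEASUREMENT_VARIABLES, PHYSIOLOGY

RACE_GROUPS = ("white", "nonwhite")

#: Raw race/ethnicity strings sampled for the nonwhite group.
NONWHITE_RACE_STRINGS = ("black", "hispanic", "asian", "other")

#: Strings that count as "no race/ethnicity data" for inclusion purposes.
MISSING_RACE_STRINGS = ("", "unknown", "declined to state")

DEFAULT_CHRONIC_PREVALENCE: dict[str, float] = {
    "metastatic_cancer": 0.04,
    "hematologic_malignancy": 0.03,
    "aids": 0.01,
    "cirrhosis": 0.05,
    "nyha_iv_heart_failure": 0.05,
    "dialysis": 0.04,
    "immunosuppression": 0.06,
}

_BASE_TIME = np.datetime64("2019-01-01T00:00")

# Mortality model: logit P(death) = intercept + age_coef * (age-60)/17
#                                  + sev_coef * severity
#                                  + bias_strength * 1[nonwhite]
# Calibrated to an overall in-hospital mortality around 30%.
_MORT_INTERCEPT = -1.1
_MORT_AGE_COEF = 0.6
_MORT_SEV_COEF = 1.4


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort; all rates are fractions in [0, 1]."""

    n_encounters: int
    nonwhite_prevalence: float = 0.18
    age_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"white": 62.0, "nonwhite": 57.0}
    )
    age_sd: float = 17.0
    age_bounds: tuple[float, float] = (18.0, 95.0)
    bias_strength: float = 0.0
    severity_sd: float = 1.0
    severity_shift_nonwhite: float = 0.5
    group_offsets: dict[str, float] = field(
        default_factory=lambda: {"spo2": 1.5, "creatinine": 0.3}
    )
    missing_rate: float = 0.2
    window_hours: int = 24
    race_missing_rate: float = 0.02
    duplicate_rate: float = 0.15
    chronic_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHRONIC_PREVALENCE)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.n_encounters, (int, np.integer)) or self.n_encounters < 0:
            raise ValueError("n_encounters must be a non-negative integer")
        for name in ("nonwhite_prevalence", "missing_rate", "race_missing_rate",
                     "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.window_hours < 1:
            raise ValueError("window_hours must be >= 1")
        if self.age_sd <= 0:
            raise ValueError("age_sd must be positive")
        if self.severity_sd <= 0:
            raise ValueError("severity_sd must be positive")
        if set(self.age_mean_by_group) != set(RACE_GROUPS):
            raise ValueError("age_mean_by_group must have keys 'white' and 'nonwhite'")
        unknown = set(self.group_offsets) - set(MEASUREMENT_VARIABLES)
        if unknown:
            raise ValueError(f"group_offsets names unknown variables: {sorted(unknown)}")
        for flag, p in self.chronic_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"chronic_prevalence[{flag!r}] must lie in [0, 1]")

    @classmethod
    def exchangeable(cls, n_encounters: int, seed: int = 0, **overrides) -> "CohortConfig":
        """A cohort in which the two race groups are statistically
        exchangeable: equal age distributions, no severity shift, no
        measurement offsets, no race-linked outcome dependence. The null
        condition for calibration checks of the bias audit."""
        base = dict(
            n_encounters=n_encounters,
            seed=seed,
            age_mean_by_group={"white": 62.0, "nonwhite": 62.0},
            severity_shift_nonwhite=0.0,
            group_offsets={},
            bias_strength=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _generate_encounter_frame(config: CohortConfig, rng: np.random.Generator):
    n = config.n_encounters
    nonwhite = rng.random(n) < config.nonwhite_prevalence
    means = np.where(
        nonwhite,
        config.age_mean_by_group["nonwhite"],
        config.age_mean_by_group["white"],
    )
    age = np.clip(rng.normal(means, config.age_sd), *config.age_bounds)
    severity = rng.normal(0.0, config.severity_sd, n)
    severity = severity + config.severity_shift_nonwhite * nonwhite

    logit = (
        _MORT_INTERCEPT
        + _MORT_AGE_COEF * (age - 60.0) / 17.0
        + _MORT_SEV_COEF * severity
        + config.bias_strength * nonwhite
    )
    outcome = (rng.random(n) < _sigmoid(logit)).astype(int)

    race = np.where(
        nonwhite,
        rng.choice(NONWHITE_RACE_STRINGS, size=n),
        "white",
    ).astype(object)
    race_missing = rng.random(n) < config.race_missing_rate
    missing_strings = rng.choice(MISSING_RACE_STRINGS, size=n)
    race[race_missing] = missing_strings[race_missing]

    flags = []
    names = sorted(config.chronic_prevalence)
    draws = {f: rng.random(n) < config.chronic_prevalence[f] for f in names}
    for i in range(n):
        flags.append(";".join(f for f in names if draws[f][i]))

    admit = _BASE_TIME + np.arange(n) * np.timedelta64(13, "m")
    encounters = pd.DataFrame(
        {
            "encounter_id": [f"e{i:06d}" for i in range(n)],
            "age": age,
            "race": race,
            "race_group": np.where(nonwhite, "nonwhite", "white"),
            "outcome": outcome,
            "admit_time": admit,
            "chronic_flags": flags,
        }
    )
    return encounters, severity, nonwhite


def _hourly_matrix(var, config, rng, severity, nonwhite):
    """(n, H) matrix of hourly values for one variable, before dropout."""
    n, H = config.n_encounters, config.window_hours
    offset = config.group_offsets.get(var, 0.0) * nonwhite

    def ar1(scale):
        e = np.empty((n, H))
        e[:, 0] = rng.normal(0.0, scale, n)
        innov_sd = scale * np.sqrt(1.0 - AR1_RHO**2)
        for h in range(1, H):
            e[:, h] = AR1_RHO * e[:, h - 1] + rng.normal(0.0, innov_sd, n)
        return e

    if var == "gcs":
        depressed = 15.0 - 2.8 * np.maximum(severity - 0.2, 0.0)
        vals = depressed[:, None] + ar1(0.7)
        return np.clip(np.round(vals), 3, 15)
    if var == "fio2":
        base = 0.21 + 0.11 * np.maximum(severity, 0.0)
        vals = base[:, None] + offset[:, None] + np.abs(ar1(0.02))
        return np.clip(vals, 0.21, 1.0)
    p = PHYSIOLOGY[var]
    centre = p.baseline + p.severity_coef * severity + offset
    centre = centre + rng.normal(0.0, p.between_sd, n)
    vals = centre[:, None] + ar1(p.hour_sd)
    return np.clip(vals, p.lo, p.hi)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (encounters, measurements) as two tidy frames.

    ``encounters`` has one row per ICU stay (encounter_id, age, race,
    race_group, outcome, admit_time, chronic_flags). ``measurements`` is
    long-format (encounter_id, timestamp, variable, value) with hourly
    events over ``window_hours``, per-(variable, hour) dropout at
    ``missing_rate``, and within-hour duplicates at ``duplicate_rate``.
    Output is a pure function of the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    encounters, severity, nonwhite = _generate_encounter_frame(config, rng)
    n, H = config.n_encounters, config.window_hours
    if n == 0:
        measurements = pd.DataFrame(
            columns=["encounter_id", "timestamp", "variable", "value"]
        ).astype({"timestamp": "datetime64[s]", "value": float})
        return encounters, measurements

    ids = encounters["encounter_id"].to_numpy()
    admit = encounters["admit_time"].to_numpy()

    frames = []
    for var in MEASUREMENT_VARIABLES:
        vals = _hourly_matrix(var, config, rng, severity, nonwhite)
        present = rng.random((n, H)) >= config.missing_rate
        dup = (rng.random((n, H)) < config.duplicate_rate) & present
        minutes = rng.integers(0, 60, size=(n, H))
        dup_minutes = rng.integers(0, 60, size=(n, H))
        jitter_scale = PHYSIOLOGY[var].hour_sd * 0.5 if var in PHYSIOLOGY else 0.3
        dup_vals = vals + rng.normal(0.0, jitter_scale, (n, H))
        if var == "gcs":
            dup_vals = np.clip(np.round(dup_vals), 3, 15)
        elif var == "fio2":
            dup_vals = np.clip(dup_vals, 0.21, 1.0)
        else:
            p = PHYSIOLOGY[var]
            dup_vals = np.clip(dup_vals, p.lo, p.hi)

        enc_idx, hour = np.nonzero(present)
        ts = admit[enc_idx] + (hour * 60 + minutes[enc_idx, hour]).astype(
            "timedelta64[m]"
        )
        frames.append(
            pd.DataFrame(
                {
                    "encounter_id": ids[enc_idx],
                    "timestamp": ts,
                    "variable": var,
                    "value": vals[enc_idx, hour],
                }
            )
        )
        d_idx, d_hour = np.nonzero(dup)
        if len(d_idx):
            ts2 = admit[d_idx] + (d_hour * 60 + dup_minutes[d_idx, d_hour]).astype(
                "timedelta64[m]"
            )
            frames.append(
                pd.DataFrame(
                    {
                        "encounter_id": ids[d_idx],
                        "timestamp": ts2,
                        "variable": var,
                        "value": dup_vals[d_idx, d_hour],
                    }
                )
            )

    measurements = pd.concat(frames, ignore_index=True)
    measurements = measurements.sort_values(
        ["encounter_id", "variable", "timestamp"], kind="stable"
    ).reset_index(drop=True)
    return encounters, measurements


def empirical_race_outcome_dependence(encounters: pd.DataFrame) -> float:
    """P(death | nonwhite) - P(death | white), from raw counts."""
    rates = encounters.groupby("race_group")["outcome"].mean()
    for group in RACE_GROUPS:
        if group not in rates.index:
            raise ValueError(f"race group {group!r} absent from the cohort")
    return float(rates["nonwhite"] - rates["white"])


def write_cohort(encounters: pd.DataFrame, measurements: pd.DataFrame, out_dir) -> None:
    """Write encounters.csv and measurements.csv (ISO-8601 timestamps)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    encounters.to_csv(out / "encounters.csv", index=False)
    measurements.to_csv(out / "measurements.csv", index=False)


def read_cohort(in_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    from pathlib import Path

    d = Path(in_dir)
    encounters = pd.read_csv(
        d / "encounters.csv", parse_dates=["admit_time"], keep_default_na=False,
        na_values=[],
    )
    encounters["outcome"] = encounters["outcome"].astype(int)
    encounters["age"] = encounters["age"].astype(float)
    measurements = pd.read_csv(d / "measurements.csv", parse_dates=["timestamp"])
    return encounters, measurements
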