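"""Rules-based severity-score engines (MEWS, SAPS II, APACHE II) and the
monotone empirical calibration of their totals to mortality probabilities.

Band boundaries live in versioned CSV rule tables under
``fairmort/rules`` (one file per score; columns: component, lower,
upper, edge inclusivity, points). Every component missing from a
snapshot contributes 0 points toward the total — the convention used
throughout this pipeline for incomplete data.

Scores are computed from the 13 captured measurements plus age and
chronic-condition flags, so only the computable subset of each
instrument is evaluated:

* SAPS II omits urine output, bilirubin, bicarbonate, oxygenation and
  admission type (each counted as a missing component, 0 points).
* APACHE II omits arterial pH and hematocrit; its oxygenation points use
  an SpO2 proxy band table (PaO2 is not captured), and mean arterial
  pressure is derived as (SBP + 2*DBP)/3. Admissions are treated as
  nonoperative, so any severe chronic-health flag adds 5 points.
* GCS values are rounded to the nearest integer before scoring (hourly
  averaging of duplicates can produce fractional values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

SCORE_NAMES = ("mews", "saps2", "apache2")

#: Chronic-health points for SAPS II (the worst applicable is taken).
SAPS2_CHRONIC_POINTS = {
    "metastatic_cancer": 9,
    "hematologic_malignancy": 10,
    "aids": 17,
}

#: Flags that qualify as severe chronic organ insufficiency or
#: immunocompromise for APACHE II (+5 points, nonoperative convention).
APACHE2_CHRONIC_FLAGS = frozenset(
    {
        "cirrhosis",
        "nyha_iv_heart_failure",
        "dialysis",
        "immunosuppression",
        "aids",
        "metastatic_cancer",
        "hematologic_malignancy",
    }
)

#: Instrument components that the captured variable set cannot supply.
UNCOMPUTABLE_COMPONENTS = {
    "mews": (),
    "saps2": ("urine_output", "bilirubin", "bicarbonate", "oxygenation",
              "admission_type"),
    "apache2": ("arterial_ph", "hematocrit"),
}


@dataclass(frozen=True)
class Band:
    lower: float
    upper: float
    lower_inclusive: bool
    upper_inclusive: bool
    points: int

    def contains(self, value: float) -> bool:
        above = value >= self.lower if self.lower_inclusive else value > self.lower
        below = value <= self.upper if self.upper_inclusive else value < self.upper
        return above and below


@lru_cache(maxsize=None)
def load_rule_table(score_name: str) -> dict[str, tuple[Band, ...]]:
    """Band tables for one score, keyed by component, validated to
    partition the real line per component."""
    if score_name not in SCORE_NAMES:
        raise ValueError(f"unknown score {score_name!r}; expected one of {SCORE_NAMES}")
    with resources.files("fairmort.rules").joinpath(f"{score_name}.csv").open() as fh:
        raw = pd.read_csv(fh)
    table: dict[str, tuple[Band, ...]] = {}
    for comp, rows in raw.groupby("component", sort=False):
        bands = [
            Band(
                lower=-np.inf if pd.isna(r.lower) else float(r.lower),
                upper=np.inf if pd.isna(r.upper) else float(r.upper),
                lower_inclusive=bool(r.lower_inclusive),
                upper_inclusive=bool(r.upper_inclusive),
                points=int(r.points),
            )
            for r in rows.itertuples()
        ]
        bands.sort(key=lambda b: b.lower)
        for a, b in zip(bands, bands[1:]):
            if a.upper != b.lower or a.upper_inclusive == b.lower_inclusive:
                raise ValueError(
                    f"{score_name}:{comp} bands do not partition the axis"
                )
        table[comp] = tuple(bands)
    return table


def band_points(bands: tuple[Band, ...], value: float) -> int:
    for band in bands:
        if band.contains(value):
            return band.points
    raise ValueError(f"value {value} not covered by any band")


_NONNEGATIVE = ("dbp", "sbp", "hr", "temp", "rr", "wbc", "platelets",
                "creatinine", "potassium", "sodium")


@dataclass(frozen=True)
class VitalsSnapshot:
    """Single per-variable values (possibly missing) for one scoring
    window, plus age and chronic-condition flags."""

    dbp: float | None = None
    sbp: float | None = None
    hr: float | None = None
    temp: float | None = None
    rr: float | None = None
    spo2: float | None = None
    wbc: float | None = None
    platelets: float | None = None
    creatinine: float | None = None
    gcs: float | None = None
    fio2: float | None = None
    potassium: float | None = None
    sodium: float | None = None
    age: float | None = None
    chronic_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in _NONNEGATIVE:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"non-physiological {name}: {v}")
        if self.gcs is not None and not 3 <= self.gcs <= 15:
            raise ValueError(f"GCS must lie in [3, 15], got {self.gcs}")
        if self.fio2 is not None and not 0.21 <= self.fio2 <= 1.0:
            raise ValueError(f"FiO2 must lie in [0.21, 1.0], got {self.fio2}")
        if self.spo2 is not None and not 0 < self.spo2 <= 100:
            raise ValueError(f"SpO2 must lie in (0, 100], got {self.spo2}")
        if self.age is not None and self.age < 0:
            raise ValueError(f"age must be non-negative, got {self.age}")


@dataclass(frozen=True)
class ScoreResult:
    total: int
    components: dict[str, int]
    n_missing_components: int


def gcs_to_avpu(gcs: float) -> int:
    """AVPU consciousness level from GCS: 15 Alert(0), 13-14 Voice(1),
    9-12 Pain(2), <=8 Unresponsive(3)."""
    g = int(round(gcs))
    if g >= 15:
        return 0
    if g >= 13:
        return 1
    if g >= 9:
        return 2
    return 3


def _score(components: dict[str, float | None], table, extra=None) -> ScoreResult:
    points: dict[str, int] = {}
    n_missing = 0
    for comp, value in components.items():
        if value is None or (isinstance(value, float) and np.isnan(value)):
            points[comp] = 0
            n_missing += 1
        else:
            points[comp] = band_points(table[comp], value)
    if extra:
        for comp, (pts, missing) in extra.items():
            points[comp] = pts
            n_missing += missing
    return ScoreResult(
        total=int(sum(points.values())),
        components=points,
        n_missing_components=n_missing,
    )


def mews_score(snapshot: VitalsSnapshot) -> ScoreResult:
    """Modified Early Warning Score: SBP, HR, RR, temperature, AVPU."""
    table = load_rule_table("mews")
    avpu = None if snapshot.gcs is None else gcs_to_avpu(snapshot.gcs)
    return _score(
        {
            "sbp": snapshot.sbp,
            "hr": snapshot.hr,
            "rr": snapshot.rr,
            "temp": snapshot.temp,
            "avpu": avpu,
        },
        table,
    )


def saps2_score(snapshot: VitalsSnapshot) -> ScoreResult:
    """SAPS II over the computable subset (HR, SBP, temperature, GCS,
    WBC, potassium, sodium, age, chronic disease)."""
    table = load_rule_table("saps2")
    gcs = None if snapshot.gcs is None else round(snapshot.gcs)
    chronic = [
        SAPS2_CHRONIC_POINTS[f]
        for f in snapshot.chronic_flags
        if f in SAPS2_CHRONIC_POINTS
    ]
    extra = {"chronic": (max(chronic, default=0), 0)}
    for comp in UNCOMPUTABLE_COMPONENTS["saps2"]:
        extra[comp] = (0, 1)
    return _score(
        {
            "hr": snapshot.hr,
            "sbp": snapshot.sbp,
            "temp": snapshot.temp,
            "gcs": gcs,
            "wbc": snapshot.wbc,
            "potassium": snapshot.potassium,
            "sodium": snapshot.sodium,
            "age": snapshot.age,
        },
        table,
        extra,
    )


def mean_arterial_pressure(sbp: float | None, dbp: float | None) -> float | None:
    if sbp is None or dbp is None:
        return None
    if np.isnan(sbp) or np.isnan(dbp):
        return None
    return (sbp + 2.0 * dbp) / 3.0


def apache2_score(snapshot: VitalsSnapshot) -> ScoreResult:
    """APACHE II acute physiology + age + chronic health points over the
    computable subset; GCS contributes 15 - GCS points."""
    table = load_rule_table("apache2")
    if snapshot.gcs is None:
        gcs_pts, gcs_missing = 0, 1
    else:
        gcs_pts, gcs_missing = 15 - int(round(snapshot.gcs)), 0
    chronic_pts = 5 if snapshot.chronic_flags & APACHE2_CHRONIC_FLAGS else 0
    extra = {"gcs": (gcs_pts, gcs_missing), "chronic": (chronic_pts, 0)}
    for comp in UNCOMPUTABLE_COMPONENTS["apache2"]:
        extra[comp] = (0, 1)
    return _score(
        {
            "temp": snapshot.temp,
            "map": mean_arterial_pressure(snapshot.sbp, snapshot.dbp),
            "hr": snapshot.hr,
            "rr": snapshot.rr,
            "spo2": snapshot.spo2,
            "sodium": snapshot.sodium,
            "potassium": snapshot.potassium,
            "creatinine": snapshot.creatinine,
            "wbc": snapshot.wbc,
            "age": snapshot.age,
        },
        table,
        extra,
    )


_SCORERS = {"mews": mews_score, "saps2": saps2_score, "apache2": apache2_score}


def score_snapshot(snapshot: VitalsSnapshot, score_name: str) -> ScoreResult:
    if score_name not in _SCORERS:
        raise ValueError(f"unknown score {score_name!r}")
    return _SCORERS[score_name](snapshot)


def _component_hourly_points(score_name: str, grid: pd.DataFrame):
    """Yield (component, hourly-values Series, hourly-points array) for
    every banded component of a score that is fed by the hourly grid."""
    table = load_rule_table(score_name)

    def pts(comp, values):
        return np.array(
            [
                -1 if pd.isna(v) else band_points(table[comp], v)
                for v in values
            ]
        )

    def row(var):
        if var in grid.index:
            return grid.loc[var]
        return pd.Series(np.nan, index=grid.columns)

    if score_name == "mews":
        for comp, var in (("sbp", "sbp"), ("hr", "hr"), ("rr", "rr"),
                          ("temp", "temp")):
            vals = row(var)
            yield comp, var, vals, pts(comp, vals)
        gcs = row("gcs")
        avpu = pd.Series(
            [np.nan if pd.isna(g) else gcs_to_avpu(g) for g in gcs],
            index=gcs.index,
        )
        yield "avpu", "gcs", gcs, pts("avpu", avpu)
    elif score_name == "saps2":
        for comp in ("hr", "sbp", "temp", "wbc", "potassium", "sodium"):
            vals = row(comp)
            yield comp, comp, vals, pts(comp, vals)
        gcs = row("gcs")
        rounded = pd.Series(
            [np.nan if pd.isna(g) else round(g) for g in gcs], index=gcs.index
        )
        yield "gcs", "gcs", gcs, pts("gcs", rounded)
    elif score_name == "apache2":
        for comp in ("temp", "hr", "rr", "spo2", "sodium", "potassium",
                     "creatinine", "wbc"):
            vals = row(comp)
            yield comp, comp, vals, pts(comp, vals)
        # GCS points are 15 - GCS: the worst hour is the lowest GCS.
        gcs = row("gcs")
        gcs_pts = np.array(
            [-1 if pd.isna(g) else 15 - int(round(g)) for g in gcs]
        )
        yield "gcs", "gcs", gcs, gcs_pts
    else:
        raise ValueError(f"unknown score {score_name!r}")


def worst_window_snapshot(
    grid: pd.DataFrame,
    score_name: str,
    age: float | None = None,
    chronic_flags: frozenset[str] = frozenset(),
) -> VitalsSnapshot:
    """Per-variable worst-in-window extraction for one encounter.

    ``grid`` is that encounter's hourly matrix (rows = variables,
    columns = hour indices). For each variable the hourly value that
    maximizes the variable's component points under the named score is
    selected (ties resolved toward the earliest hour); variables missing
    at every hour stay missing. For APACHE II the mean arterial pressure
    is formed per hour from SBP and DBP and the SBP/DBP pair of the
    worst-MAP hour is carried into the snapshot.
    """
    if score_name not in SCORE_NAMES:
        raise ValueError(f"unknown score {score_name!r}")
    values: dict[str, float] = {}
    for comp, var, vals, pts in _component_hourly_points(score_name, grid):
        if (pts >= 0).any():
            best = int(np.argmax(pts))
            if var not in values or comp != "avpu":
                values[var] = float(vals.iloc[best])
    if score_name == "apache2" and "sbp" in grid.index and "dbp" in grid.index:
        table = load_rule_table("apache2")
        sbp, dbp = grid.loc["sbp"], grid.loc["dbp"]
        both = sbp.notna() & dbp.notna()
        if both.any():
            maps = (sbp[both] + 2.0 * dbp[both]) / 3.0
            pts = np.array([band_points(table["map"], m) for m in maps])
            best = maps.index[int(np.argmax(pts))]
            values["sbp"] = float(sbp.loc[best])
            values["dbp"] = float(dbp.loc[best])
    return VitalsSnapshot(age=age, chronic_flags=frozenset(chronic_flags), **values)


def score_encounters(
    grid: pd.DataFrame, encounters: pd.DataFrame, score_name: str
) -> pd.Series:
    """Worst-in-window score totals for every encounter in a cohort-wide
    hourly grid (MultiIndex columns (variable, hour))."""
    enc = encounters.set_index("encounter_id")
    totals = {}
    for enc_id, row in grid.iterrows():
        sub = row.unstack("hour") if isinstance(row.index, pd.MultiIndex) else row
        flags = enc.loc[enc_id, "chronic_flags"]
        flags = frozenset(f for f in str(flags).split(";") if f) if pd.notna(flags) else frozenset()
        snap = worst_window_snapshot(
            sub, score_name, age=float(enc.loc[enc_id, "age"]), chronic_flags=flags
        )
        totals[enc_id] = score_snapshot(snap, score_name).total
    return pd.Series(totals, name=f"{score_name}_score").rename_axis("encounter_id")


@dataclass(frozen=True)
class CalibrationMap:
    """Monotone mapping from integer score to mortality probability.

    ``scores`` covers every integer between the smallest and largest
    score observed in training; ``probs`` is non-decreasing.
    """

    scores: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.probs) < 0):
            raise ValueError("calibration probabilities must be non-decreasing")

    def __call__(self, score) -> np.ndarray | float:
        """Exact lookup; scores outside the training domain clamp to the
        nearest endpoint probability."""
        idx = np.searchsorted(self.scores, np.asarray(score))
        idx = np.clip(idx, 0, len(self.scores) - 1)
        out = self.probs[idx]
        if np.ndim(score) == 0:
            return float(out)
        return out


def calibrate_scores(train_scores, train_outcomes) -> CalibrationMap:
    """Empirical score-to-mortality calibration with monotone carry-forward.

    Each observed score maps to the death fraction among training
    encounters with that score; scanning scores in increasing order, any
    probability below the running maximum is raised to it, and
    unobserved intermediate scores inherit the running maximum.
    """
    s = np.asarray(train_scores)
    y = np.asarray(train_outcomes)
    if len(s) == 0:
        raise ValueError("calibration requires at least one training example")
    if len(s) != len(y):
        raise ValueError("scores and outcomes must be aligned")
    rates = pd.Series(y).groupby(pd.Series(s)).mean()
    domain = np.arange(int(rates.index.min()), int(rates.index.max()) + 1)
    probs = np.empty(len(domain))
    running = 0.0
    for i, score in enumerate(domain):
        if score in rates.index:
            running = max(running, float(rates.loc[score]))
        probs[i] = running
    return CalibrationMap(scores=domain, probs=probs)


def apply_calibration(cal: CalibrationMap, score):
    return cal(score)
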