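"""Cohort preparation: inclusion criteria, hourly binning, percentile
outlier nulling, and feature-matrix assembly.

An encounter enters the analysis only if its measurement stream spans at
least ``min_hours`` distinct hours after ICU admission, contains every
one of the 13 variables at least once, and carries usable race/ethnicity
data. Multiple values of one variable within an hour are averaged; hour
bins are half-open intervals [h, h+1) from admission. Values strictly
outside the cohort-wide 1st/99th percentiles of their variable are
nulled to missing; missingness is then passed through to the learner,
which must accept it natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fair_reweighting import assign_age_strata
from .synthetic_cohort import MISSING_RACE_STRINGS
from .variables import MEASUREMENT_VARIABLES

EXCLUSION_REASONS = ("insufficient_hours", "missing_variables", "no_race_data")


def _check_variables(measurements: pd.DataFrame) -> None:
    unknown = set(measurements["variable"].unique()) - set(MEASUREMENT_VARIABLES)
    if unknown:
        raise ValueError(f"unknown measurement variables: {sorted(unknown)}")


def _hour_index(measurements: pd.DataFrame, encounters: pd.DataFrame) -> pd.Series:
    admit = encounters.set_index("encounter_id")["admit_time"]
    delta = measurements["timestamp"].to_numpy() - admit.loc[
        measurements["encounter_id"]
    ].to_numpy()
    return pd.Series(
        delta // np.timedelta64(1, "h"), index=measurements.index, name="hour"
    ).astype(int)


def apply_inclusion_criteria(
    encounters: pd.DataFrame,
    measurements: pd.DataFrame,
    min_hours: int = 10,
) -> tuple[pd.Index, dict[str, int]]:
    """Return (included encounter ids, tally of exclusions by reason).

    Each excluded encounter is attributed to its first failing criterion,
    in the order: insufficient hours, missing variables, no race data.
    """
    _check_variables(measurements)
    hour = _hour_index(measurements, encounters)
    by_enc = measurements.assign(hour=hour).groupby("encounter_id")
    distinct_hours = by_enc["hour"].nunique()
    n_vars = by_enc["variable"].nunique()

    ids = encounters["encounter_id"]
    hours_ok = ids.map(distinct_hours).fillna(0).ge(min_hours)
    vars_ok = ids.map(n_vars).fillna(0).eq(len(MEASUREMENT_VARIABLES))
    race = encounters["race"].fillna("").astype(str).str.strip().str.lower()
    race_ok = ~race.isin(MISSING_RACE_STRINGS)

    tally = dict.fromkeys(EXCLUSION_REASONS, 0)
    tally["insufficient_hours"] = int((~hours_ok).sum())
    tally["missing_variables"] = int((hours_ok & ~vars_ok).sum())
    tally["no_race_data"] = int((hours_ok & vars_ok & ~race_ok).sum())
    included = ids[hours_ok & vars_ok & race_ok]
    tally["included"] = int(len(included))
    return pd.Index(included), tally


def bin_hourly(
    measurements: pd.DataFrame,
    encounters: pd.DataFrame,
    window_hours: int = 24,
    encounter_ids=None,
) -> pd.DataFrame:
    """Hour-binned measurement matrix.

    Returns a DataFrame indexed by encounter_id with MultiIndex columns
    (variable, hour) for hour 0..window_hours-1; cell = arithmetic mean
    of the variable's values within [admit+h, admit+h+1), NaN if none.
    Events at or beyond the window end are ignored; an event before
    admission raises (it signals an extraction bug upstream).
    """
    _check_variables(measurements)
    if encounter_ids is not None:
        measurements = measurements[
            measurements["encounter_id"].isin(encounter_ids)
        ]
    hour = _hour_index(measurements, encounters)
    if (hour < 0).any():
        bad = measurements.loc[hour < 0, "encounter_id"].iloc[0]
        raise ValueError(f"measurement before admission time (encounter {bad!r})")
    in_window = hour < window_hours
    binned = (
        measurements[in_window]
        .assign(hour=hour[in_window])
        .groupby(["encounter_id", "variable", "hour"], sort=True)["value"]
        .mean()
    )
    wide = binned.unstack(["variable", "hour"])
    full_cols = pd.MultiIndex.from_product(
        [list(MEASUREMENT_VARIABLES), range(window_hours)],
        names=["variable", "hour"],
    )
    wide = wide.reindex(columns=full_cols)
    rows = encounter_ids if encounter_ids is not None else encounters["encounter_id"]
    wide = wide.reindex(pd.Index(rows, name="encounter_id"))
    return wide.sort_index()


def remove_outliers(
    grid: pd.DataFrame,
    lower_pct: float = 1.0,
    upper_pct: float = 99.0,
    thresholds: dict[str, tuple[float, float]] | None = None,
) -> tuple[pd.DataFrame, dict[str, int], dict[str, tuple[float, float]]]:
    """Null values strictly outside per-variable cohort percentiles.

    Percentiles use linear interpolation between order statistics and are
    computed once over all (encounter, hour) cells of each variable;
    precomputed ``thresholds`` may be supplied instead (re-application
    with the same thresholds is a no-op). Returns the cleaned grid, the
    per-variable removal counts, and the thresholds used.
    """
    out = grid.copy()
    removed: dict[str, int] = {}
    used: dict[str, tuple[float, float]] = {}
    for var in grid.columns.get_level_values("variable").unique():
        block = grid[var]
        values = block.to_numpy().ravel()
        values = values[~np.isnan(values)]
        if thresholds is not None and var in thresholds:
            lo, hi = thresholds[var]
        else:
            if len(values) < 2:
                warnings.warn(
                    f"variable {var!r} has <2 observed values; outlier pass skipped"
                )
                removed[var] = 0
                continue
            lo = float(np.percentile(values, lower_pct))
            hi = float(np.percentile(values, upper_pct))
        mask = (block < lo) | (block > hi)
        removed[var] = int(mask.to_numpy().sum())
        used[var] = (lo, hi)
        out[var] = block.mask(mask)
    return out, removed, used


@dataclass
class FeatureMatrix:
    """Model-ready design matrix with aligned labels and group vectors.

    Rows are included encounters sorted by encounter_id; columns are one
    per (variable, hour) pair named ``{variable}_h{hour}`` plus ``age``.
    Missing cells stay NaN — the learner must accept them natively.
    """

    X: pd.DataFrame
    y: pd.Series
    group: pd.Series
    stratum: pd.Series

    @property
    def encounter_ids(self) -> pd.Index:
        return self.X.index

    def __len__(self) -> int:
        return len(self.X)


def build_features(grid: pd.DataFrame, encounters: pd.DataFrame) -> FeatureMatrix:
    """Flatten an hourly grid into a FeatureMatrix (plus an age column)."""
    enc = encounters.set_index("encounter_id")
    missing = grid.index.difference(enc.index)
    if len(missing):
        raise ValueError(f"grid contains encounters absent from the encounter table: "
                         f"{list(missing[:5])}")
    grid = grid.sort_index()
    X = grid.copy()
    X.columns = [f"{var}_h{hour}" for var, hour in grid.columns]
    X["age"] = enc.loc[X.index, "age"].astype(float)
    y = enc.loc[X.index, "outcome"].astype(int).rename("outcome")
    group = enc.loc[X.index, "race_group"].rename("group")
    stratum = pd.Series(
        assign_age_strata(X["age"].to_numpy()), index=X.index, name="stratum"
    )
    return FeatureMatrix(X=X, y=y, group=group, stratum=stratum)


def feature_columns(window_hours: int) -> list[str]:
    cols = [
        f"{var}_h{hour}"
        for var in MEASUREMENT_VARIABLES
        for hour in range(window_hours)
    ]
    return cols + ["age"]


def write_features(fm: FeatureMatrix, path) -> None:
    out = fm.X.copy()
    out.insert(0, "outcome", fm.y)
    out.insert(1, "race_group", fm.group)
    out.insert(2, "stratum", fm.stratum)
    out.to_csv(path, index=True, index_label="encounter_id")


def read_features(path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="encounter_id")
    y = df.pop("outcome").astype(int)
    group = df.pop("race_group").rename("group")
    stratum = df.pop("stratum")
    return FeatureMatrix(X=df, y=y, group=group, stratum=stratum)
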