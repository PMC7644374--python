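import numpy as np
import pandas as pd
import pytest

from fairmort.cohort_prep import (
    apply_inclusion_criteria,
    bin_hourly,
    build_features,
    remove_outliers,
)
from fairmort.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-encounter biased cohort over a 10-hour window."""
    config = CohortConfig(
        n_encounters=400, window_hours=10, bias_strength=0.8, seed=7
    )
    encounters, measurements = generate_cohort(config)
    return config, encounters, measurements


@pytest.fixture(scope="session")
def prepared(small_cohort):
    """(feature matrix, cleaned hourly grid, encounters) for the small cohort."""
    _, encounters, measurements = small_cohort
    included, _ = apply_inclusion_criteria(encounters, measurements, min_hours=10)
    grid = bin_hourly(measurements, encounters, 10, encounter_ids=included)
    grid, _, _ = remove_outliers(grid)
    fm = build_features(grid, encounters[encounters["encounter_id"].isin(included)])
    return fm, grid, encounters


def tiny_measurements(rows, admit="2020-01-01 00:00"):
    """Build a measurement frame from (encounter_id, minutes_after_admit,
    variable, value) tuples, with all encounters admitted at ``admit``."""
    base = pd.Timestamp(admit)
    return pd.DataFrame(
        {
            "encounter_id": [r[0] for r in rows],
            "timestamp": [base + pd.Timedelta(minutes=r[1]) for r in rows],
            "variable": [r[2] for r in rows],
            "value": [float(r[3]) for r in rows],
        }
    )


def tiny_encounters(ids, admit="2020-01-01 00:00", race="white", age=50.0):
    base = pd.Timestamp(admit)
    n = len(ids)
    return pd.DataFrame(
        {
            "encounter_id": list(ids),
            "age": [age] * n,
            "race": [race] * n,
            "race_group": ["white" if race == "white" else "nonwhite"] * n,
            "outcome": [0] * n,
            "admit_time": [base] * n,
            "chronic_flags": [""] * n,
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
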