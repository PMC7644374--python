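"""Reweighting preprocessing: demographic prevalence ratios within age strata.

Training examples are partitioned into seven age strata; within each
stratum every (race group g, outcome y) cell receives the weight

    w(s, g, y) = P_expected(g, y) / P_observed(g, y)
               = (N_sg * N_sy) / (N_s * N_sgy)

i.e. the ratio of the cell probability expected under independence of
group and outcome to the observed cell probability (Kamiran & Calders
style reweighing). In any stratum whose four cells are all populated,
the weighted joint distribution of (group, outcome) factorizes exactly,
so the weighted death rate is identical across race groups. When a
stratum contains a single race group (or a single outcome), the formula
collapses to weight 1 for every present cell — neutrality by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STRATUM_LABELS = ("<18", "18-29", "30-39", "40-49", "50-59", "60-69", ">=70")

_EDGES = np.array([18, 30, 40, 50, 60, 70])


def assign_age_stratum(age: float) -> str:
    """Age stratum from age in completed years (integer truncation)."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return STRATUM_LABELS[int(np.digitize(np.floor(age), _EDGES))]


def assign_age_strata(ages) -> np.ndarray:
    ages = np.asarray(ages, dtype=float)
    if (ages < 0).any():
        raise ValueError("ages must be non-negative")
    idx = np.digitize(np.floor(ages), _EDGES)
    return np.asarray(STRATUM_LABELS, dtype=object)[idx]


@dataclass
class CellWeights:
    """Per-(stratum, group, outcome) counts and demographic prevalence
    ratios, as a tidy table with columns
    [stratum, group, outcome, count, weight]."""

    table: pd.DataFrame

    def weight(self, stratum: str, group: str, outcome: int) -> float:
        t = self.table
        row = t[
            (t["stratum"] == stratum)
            & (t["group"] == group)
            & (t["outcome"] == outcome)
        ]
        if row.empty:
            raise KeyError(f"empty cell ({stratum}, {group}, {outcome})")
        return float(row["weight"].iloc[0])


def compute_reweights(
    strata, groups, outcomes
) -> tuple[CellWeights, np.ndarray]:
    """Cell weights and their per-example expansion.

    Inputs are aligned vectors of stratum label, race group, and binary
    outcome. Every example receives the weight of its (stratum, group,
    outcome) cell; weights are strictly positive and finite.
    """
    df = pd.DataFrame(
        {
            "stratum": np.asarray(strata, dtype=object),
            "group": np.asarray(groups, dtype=object),
            "outcome": np.asarray(outcomes, dtype=int),
        }
    )
    if len(df) == 0:
        raise ValueError("at least one example is required")
    if not df["outcome"].isin((0, 1)).all():
        raise ValueError("outcomes must be binary 0/1")

    n_s = df.groupby("stratum")["outcome"].transform("size")
    n_sg = df.groupby(["stratum", "group"])["outcome"].transform("size")
    n_sy = df.groupby(["stratum", "outcome"])["group"].transform("size")
    n_sgy = df.groupby(["stratum", "group", "outcome"])["stratum"].transform("size")
    sample_weights = (
        n_sg.to_numpy() * n_sy.to_numpy() / (n_s.to_numpy() * n_sgy.to_numpy())
    )

    cells = (
        df.assign(weight=sample_weights)
        .groupby(["stratum", "group", "outcome"], as_index=False)
        .agg(count=("weight", "size"), weight=("weight", "first"))
    )
    return CellWeights(cells), sample_weights


def write_weights(fm, sample_weights, path) -> None:
    """weights.csv: encounter_id, stratum, group, outcome, weight."""
    pd.DataFrame(
        {
            "encounter_id": fm.encounter_ids,
            "stratum": fm.stratum.to_numpy(),
            "group": fm.group.to_numpy(),
            "outcome": fm.y.to_numpy(),
            "weight": sample_weights,
        }
    ).to_csv(path, index=False)
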