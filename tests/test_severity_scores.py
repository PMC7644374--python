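"""Score engines are checked against independently written band-table
oracles (if/elif encodings of the published instruments, kept deliberately
separate from the packaged CSV rule data) on large random snapshot samples,
plus the hand-worked examples."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fairmort.severity_scores import (
    CalibrationMap,
    VitalsSnapshot,
    apache2_score,
    apply_calibration,
    calibrate_scores,
    gcs_to_avpu,
    mews_score,
    saps2_score,
    score_snapshot,
    worst_window_snapshot,
)

# ---------------------------------------------------------------- oracles


def mews_oracle(s):
    # integer band edges extended to continuous values half-open, matching
    # the package's documented convention
    pts = 0
    if s.sbp is not None:
        v = s.sbp
        pts += 3 if v < 71 else 2 if v < 81 else 1 if v < 101 else \
            0 if v < 200 else 2
    if s.hr is not None:
        v = s.hr
        pts += 2 if v < 41 else 1 if v < 51 else 0 if v < 101 else \
            1 if v < 111 else 2 if v < 130 else 3
    if s.rr is not None:
        v = s.rr
        pts += 2 if v < 9 else 0 if v < 15 else 1 if v < 21 else \
            2 if v < 30 else 3
    if s.temp is not None:
        v = s.temp
        pts += 2 if v < 35 else 0 if v < 38.5 else 2
    if s.gcs is not None:
        g = round(s.gcs)
        pts += 0 if g == 15 else 1 if g >= 13 else 2 if g >= 9 else 3
    return pts


def saps2_oracle(s):
    pts = 0
    if s.hr is not None:
        v = s.hr
        pts += 11 if v < 40 else 2 if v < 70 else 0 if v < 120 else \
            4 if v < 160 else 7
    if s.sbp is not None:
        v = s.sbp
        pts += 13 if v < 70 else 5 if v < 100 else 0 if v < 200 else 2
    if s.temp is not None:
        pts += 3 if s.temp >= 39 else 0
    if s.gcs is not None:
        g = round(s.gcs)
        pts += 26 if g < 6 else 13 if g <= 8 else 7 if g <= 10 else \
            5 if g <= 13 else 0
    if s.wbc is not None:
        v = s.wbc
        pts += 12 if v < 1 else 0 if v < 20 else 3
    if s.potassium is not None:
        v = s.potassium
        pts += 3 if v < 3 else 0 if v < 5 else 3
    if s.sodium is not None:
        v = s.sodium
        pts += 5 if v < 125 else 0 if v < 145 else 1
    if s.age is not None:
        a = s.age
        pts += 0 if a < 40 else 7 if a < 60 else 12 if a < 70 else \
            15 if a < 75 else 16 if a < 80 else 18
    chronic = {"aids": 17, "hematologic_malignancy": 10, "metastatic_cancer": 9}
    applicable = [chronic[f] for f in s.chronic_flags if f in chronic]
    pts += max(applicable) if applicable else 0
    return pts


def apache2_oracle(s):
    pts = 0
    if s.temp is not None:
        v = s.temp
        pts += 4 if v >= 41 else 3 if v >= 39 else 1 if v >= 38.5 else \
            0 if v >= 36 else 1 if v >= 34 else 2 if v >= 32 else \
            3 if v >= 30 else 4
    if s.sbp is not None and s.dbp is not None:
        m = (s.sbp + 2 * s.dbp) / 3
        pts += 4 if m >= 160 else 3 if m >= 130 else 2 if m >= 110 else \
            0 if m >= 70 else 2 if m >= 50 else 4
    if s.hr is not None:
        v = s.hr
        pts += 4 if v >= 180 else 3 if v >= 140 else 2 if v >= 110 else \
            0 if v >= 70 else 2 if v >= 55 else 3 if v >= 40 else 4
    if s.rr is not None:
        v = s.rr
        pts += 4 if v >= 50 else 3 if v >= 35 else 1 if v >= 25 else \
            0 if v >= 12 else 1 if v >= 10 else 2 if v >= 6 else 4
    if s.spo2 is not None:
        v = s.spo2
        pts += 0 if v >= 96 else 1 if v >= 91 else 3 if v >= 86 else 4
    if s.sodium is not None:
        v = s.sodium
        pts += 4 if v >= 180 else 3 if v >= 160 else 2 if v >= 155 else \
            1 if v >= 150 else 0 if v >= 130 else 2 if v >= 120 else \
            3 if v >= 111 else 4
    if s.potassium is not None:
        v = s.potassium
        pts += 4 if v >= 7 else 3 if v >= 6 else 1 if v >= 5.5 else \
            0 if v >= 3.5 else 1 if v >= 3 else 2 if v >= 2.5 else 4
    if s.creatinine is not None:
        v = s.creatinine
        pts += 4 if v >= 3.5 else 3 if v >= 2 else 2 if v >= 1.5 else \
            0 if v >= 0.6 else 2
    if s.wbc is not None:
        v = s.wbc
        pts += 4 if v >= 40 else 2 if v >= 20 else 1 if v >= 15 else \
            0 if v >= 3 else 2 if v >= 1 else 4
    if s.gcs is not None:
        pts += 15 - round(s.gcs)
    if s.age is not None:
        a = s.age
        pts += 0 if a < 45 else 2 if a < 55 else 3 if a < 65 else \
            5 if a < 75 else 6
    severe = {"cirrhosis", "nyha_iv_heart_failure", "dialysis",
              "immunosuppression", "aids", "metastatic_cancer",
              "hematologic_malignancy"}
    pts += 5 if s.chronic_flags & severe else 0
    return pts


ORACLES = {"mews": mews_oracle, "saps2": saps2_oracle, "apache2": apache2_oracle}

_RANGES = {
    "dbp": (20, 140), "sbp": (40, 250), "hr": (20, 220), "temp": (29, 42.5),
    "rr": (4, 60), "spo2": (56, 100), "wbc": (0.2, 60), "platelets": (5, 900),
    "creatinine": (0.2, 8), "fio2": (0.21, 1.0), "potassium": (1.8, 8.5),
    "sodium": (105, 190),
}

_FLAGS = ("metastatic_cancer", "hematologic_malignancy", "aids", "cirrhosis",
          "nyha_iv_heart_failure", "dialysis", "immunosuppression")


def random_snapshot(rng, present_prob=0.8):
    kwargs = {}
    for var, (lo, hi) in _RANGES.items():
        if rng.random() < present_prob:
            v = rng.uniform(lo, hi)
            if var != "fio2" and rng.random() < 0.3:  # hit integer band edges
                v = float(np.clip(round(v), lo, hi))
            kwargs[var] = v
    if rng.random() < present_prob:
        kwargs["gcs"] = int(rng.integers(3, 16))
    if rng.random() < present_prob:
        kwargs["age"] = float(rng.uniform(18, 95))
    flags = frozenset(f for f in _FLAGS if rng.random() < 0.1)
    return VitalsSnapshot(chronic_flags=flags, **kwargs)


# ----------------------------------------------------------------- tests


@pytest.mark.parametrize("score_name", ["mews", "saps2", "apache2"])
def test_engine_matches_oracle_on_random_snapshots(score_name, rng):
    oracle = ORACLES[score_name]
    for _ in range(1000):
        snap = random_snapshot(rng)
        result = score_snapshot(snap, score_name)
        assert result.total == oracle(snap), snap
        assert result.total == sum(result.components.values())
        assert all(p >= 0 for p in result.components.values())


@pytest.mark.parametrize("score_name", ["mews", "saps2", "apache2"])
def test_blanking_a_component_never_raises_the_total(score_name, rng):
    """Missing components contribute 0 points, so nulling any present
    variable can only keep or reduce the total."""
    import dataclasses

    for _ in range(200):
        snap = random_snapshot(rng)
        total = score_snapshot(snap, score_name).total
        present = [
            f.name for f in dataclasses.fields(snap)
            if f.name not in ("chronic_flags",) and getattr(snap, f.name) is not None
        ]
        if not present:
            continue
        drop = present[int(rng.integers(len(present)))]
        reduced = dataclasses.replace(snap, **{drop: None})
        assert score_snapshot(reduced, score_name).total <= total


def test_all_missing_scores_zero():
    empty = VitalsSnapshot()
    assert mews_score(empty).total == 0
    assert mews_score(empty).n_missing_components == 5
    assert saps2_score(empty).total == 0
    assert apache2_score(empty).total == 0


def test_mews_hand_examples():
    assert mews_score(
        VitalsSnapshot(sbp=120, hr=80, rr=12, temp=37.0, gcs=15)
    ).total == 0
    result = mews_score(VitalsSnapshot(sbp=85, hr=105, rr=22, temp=36.5, gcs=15))
    assert result.total == 4
    assert result.components == {"sbp": 1, "hr": 1, "rr": 2, "temp": 0, "avpu": 0}


def test_saps2_hand_examples():
    assert saps2_score(
        VitalsSnapshot(hr=80, sbp=120, temp=37.0, gcs=15, wbc=8, potassium=4.0,
                       sodium=140, age=30)
    ).total == 0
    result = saps2_score(VitalsSnapshot(hr=165, age=30))
    assert result.components["hr"] == 7
    assert result.total == 7


def test_apache2_hand_examples():
    assert apache2_score(VitalsSnapshot(gcs=12, age=30)).total == 3
    result = apache2_score(VitalsSnapshot(temp=41.2, age=30))
    assert result.components["temp"] == 4
    assert result.total == 4


def test_gcs_to_avpu_mapping():
    assert gcs_to_avpu(15) == 0
    assert gcs_to_avpu(13) == 1 and gcs_to_avpu(14) == 1
    assert gcs_to_avpu(9) == 2 and gcs_to_avpu(12) == 2
    assert gcs_to_avpu(8) == 3 and gcs_to_avpu(3) == 3


def test_non_physiological_value_rejected():
    with pytest.raises(ValueError, match="hr"):
        VitalsSnapshot(hr=-5)
    with pytest.raises(ValueError, match="GCS"):
        VitalsSnapshot(gcs=2)
    with pytest.raises(ValueError, match="FiO2"):
        VitalsSnapshot(fio2=0.1)


# ------------------------------------------------------ worst-in-window


def _grid(**rows):
    hours = max(len(v) for v in rows.values())
    df = pd.DataFrame(np.nan, index=list(rows), columns=range(hours))
    for var, vals in rows.items():
        df.loc[var, : len(vals) - 1] = vals
    return df


def test_worst_window_picks_points_maximizer():
    grid = _grid(hr=[80.0, 150.0, 90.0])
    snap = worst_window_snapshot(grid, "saps2")
    assert snap.hr == 150.0  # 4 points under SAPS II vs 0 for the others


def test_worst_window_constant_variable():
    grid = _grid(temp=[37.0, 37.0, 37.0])
    assert worst_window_snapshot(grid, "mews").temp == 37.0


def test_worst_window_all_missing_stays_missing():
    grid = _grid(hr=[np.nan, np.nan])
    assert worst_window_snapshot(grid, "mews").hr is None


def test_worst_window_tie_breaks_to_earliest_hour():
    grid = _grid(hr=[112.0, 125.0])  # both 2 MEWS points
    assert worst_window_snapshot(grid, "mews").hr == 112.0


def test_worst_window_unknown_score_errors():
    with pytest.raises(ValueError, match="unknown score"):
        worst_window_snapshot(_grid(hr=[80.0]), "sofa")


def test_worst_window_total_dominates_every_hour(rng):
    """The worst-in-window score is >= the score of any single hour."""
    from fairmort.variables import MEASUREMENT_VARIABLES

    for _ in range(25):
        hours = 5
        data = {}
        for var in MEASUREMENT_VARIABLES:
            lo, hi = _RANGES.get(var, (3, 15))
            vals = rng.uniform(lo, hi, hours)
            if var == "gcs":
                vals = np.round(np.clip(vals, 3, 15))
            vals[rng.random(hours) < 0.3] = np.nan
            data[var] = vals
        grid = pd.DataFrame(data).T
        for score_name in ("mews", "saps2", "apache2"):
            worst = score_snapshot(
                worst_window_snapshot(grid, score_name, age=50.0), score_name
            ).total
            for h in range(hours):
                col = grid[h]
                kwargs = {
                    v: (None if pd.isna(col[v]) else float(col[v]))
                    for v in grid.index
                }
                hourly = score_snapshot(
                    VitalsSnapshot(age=50.0, **kwargs), score_name
                ).total
                assert worst >= hourly


# --------------------------------------------------------- calibration


def running_max_oracle(scores, outcomes):
    """Brute-force carry-forward calibration."""
    raw = {}
    for s in sorted(set(scores)):
        members = [y for sc, y in zip(scores, outcomes) if sc == s]
        raw[s] = sum(members) / len(members)
    out = {}
    running = 0.0
    for s in range(min(raw), max(raw) + 1):
        if s in raw:
            running = max(running, raw[s])
        out[s] = running
    return out


def test_calibration_hand_example():
    scores = [0] * 10 + [1] * 10 + [2] * 20 + [3] * 10
    outcomes = [1] * 1 + [0] * 9 + [1] * 3 + [0] * 7 + [1] * 5 + [0] * 15 + \
        [1] * 4 + [0] * 6
    cal = calibrate_scores(scores, outcomes)
    assert list(cal.probs) == pytest.approx([0.1, 0.3, 0.3, 0.4])


def test_calibration_monotone_input_is_identity():
    scores = [0] * 4 + [1] * 4 + [2] * 4
    outcomes = [0, 0, 0, 0, 1, 0, 0, 0, 1, 1, 0, 0]
    cal = calibrate_scores(scores, outcomes)
    assert list(cal.probs) == pytest.approx([0.0, 0.25, 0.5])


def test_calibration_single_score_degenerate():
    cal = calibrate_scores([5, 5, 5], [1, 0, 1])
    assert list(cal.scores) == [5]
    assert cal(5) == pytest.approx(2 / 3)


def test_calibration_empty_errors():
    with pytest.raises(ValueError):
        calibrate_scores([], [])


def test_calibration_matches_oracle_on_random_instances(rng):
    for _ in range(1000):
        n = int(rng.integers(1, 60))
        scores = rng.integers(0, 12, n).tolist()
        outcomes = (rng.random(n) < 0.3).astype(int).tolist()
        cal = calibrate_scores(scores, outcomes)
        oracle = running_max_oracle(scores, outcomes)
        assert list(cal.scores) == sorted(oracle)
        assert list(cal.probs) == pytest.approx([oracle[s] for s in cal.scores])
        assert np.all(np.diff(cal.probs) >= 0)


def test_apply_calibration_extrapolates_to_endpoints():
    cal = calibrate_scores([2] * 5 + [4] * 5, [0, 0, 0, 0, 1] + [1, 1, 1, 0, 0])
    assert apply_calibration(cal, 2) == pytest.approx(0.2)
    assert apply_calibration(cal, 0) == pytest.approx(0.2)   # below domain
    assert apply_calibration(cal, 99) == pytest.approx(0.6)  # above domain
    assert apply_calibration(cal, 3) == pytest.approx(0.2)   # unobserved interior


@settings(derandomize=True, max_examples=60)
@given(
    st.lists(
        st.tuples(st.integers(0, 15), st.integers(0, 1)), min_size=2, max_size=80
    )
)
def test_calibration_is_always_monotone(pairs):
    scores = [p[0] for p in pairs]
    outcomes = [p[1] for p in pairs]
    cal = calibrate_scores(scores, outcomes)
    probs = cal(np.arange(-2, 20))
    assert np.all(np.diff(probs) >= 0)
    assert np.all((probs >= 0) & (probs <= 1))


def test_calibration_map_rejects_decreasing_probs():
    with pytest.raises(ValueError):
        CalibrationMap(scores=np.array([0, 1]), probs=np.array([0.5, 0.4]))
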