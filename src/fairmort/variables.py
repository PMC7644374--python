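"""Closed vocabulary of the 13 hourly patient measurements and their
population physiology used by the synthetic cohort generator.

Each variable has a healthy baseline, a between-patient spread, a
severity coefficient (how far one standard deviation of latent illness
severity displaces the value, signed in the clinically deranged
direction), an hour-to-hour AR(1) innovation scale, and physiological
clip bounds. Glasgow coma scale and FiO2 are handled by dedicated rules
in the generator (integer-valued / floor-bounded respectively).
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical measurement names, in the conventional reporting order.
MEASUREMENT_VARIABLES: tuple[str, ...] = (
    "dbp",          # diastolic blood pressure, mmHg
    "sbp",          # systolic blood pressure, mmHg
    "hr",           # heart rate, beats/min
    "temp",         # body temperature, deg C
    "rr",           # respiratory rate, breaths/min
    "spo2",         # peripheral oxygen saturation, %
    "wbc",          # white blood cell count, 10^3/uL
    "platelets",    # platelet count, 10^3/uL
    "creatinine",   # serum creatinine, mg/dL
    "gcs",          # Glasgow coma scale, integer 3-15
    "fio2",         # fraction of inspired oxygen, 0.21-1.0
    "potassium",    # serum potassium, mEq/L
    "sodium",       # serum sodium, mEq/L
)


@dataclass(frozen=True)
class Physiology:
    baseline: float
    between_sd: float
    severity_coef: float
    hour_sd: float
    lo: float
    hi: float


#: Gaussian physiology for the eleven continuously distributed variables.
PHYSIOLOGY: dict[str, Physiology] = {
    "dbp": Physiology(68.0, 8.0, -6.0, 3.0, 20.0, 140.0),
    "sbp": Physiology(118.0, 12.0, -12.0, 5.0, 40.0, 250.0),
    "hr": Physiology(82.0, 10.0, 14.0, 5.0, 20.0, 220.0),
    "temp": Physiology(36.8, 0.35, 0.55, 0.2, 32.0, 42.5),
    "rr": Physiology(16.0, 2.5, 4.5, 1.5, 4.0, 60.0),
    "spo2": Physiology(97.0, 1.2, -2.8, 0.8, 55.0, 100.0),
    "wbc": Physiology(8.5, 2.2, 4.0, 1.0, 0.2, 80.0),
    "platelets": Physiology(250.0, 60.0, -45.0, 15.0, 5.0, 1000.0),
    "creatinine": Physiology(1.0, 0.3, 0.7, 0.1, 0.2, 12.0),
    "potassium": Physiology(4.1, 0.4, 0.4, 0.15, 1.8, 9.0),
    "sodium": Physiology(139.0, 3.0, -2.5, 1.0, 110.0, 175.0),
}

#: Hour-to-hour autocorrelation shared by all variables.
AR1_RHO = 0.7
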