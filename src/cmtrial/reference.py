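"""Published group-level summary statistics of the original trial cohort.

The trial's patient-level data were never released; what is public are the
printed summary tables. These constants are inputs to the verification
harness: dosing consistency checks re-derive IDR/TIL from the printed mean
flow rates and volumes, and the proportion tests reconstruct integer counts
from the printed percentages before re-running the chi-square comparisons.
All values are per arm (BW / LBW / CO) unless noted.
"""

from __future__ import annotations

from .protocol import Arm

#: Randomized patients per arm (intention-to-treat).
GROUP_N = {Arm.BW: 112, Arm.LBW: 108, Arm.CO: 107}

#: Patients excluded from the per-protocol population, per arm (41 total).
PP_EXCLUSIONS = {Arm.BW: 13, Arm.LBW: 17, Arm.CO: 11}

#: Cohort-level baseline means (pooled across arms).
COHORT_MEANS = {
    "age_years": 60.0,
    "height_cm": 173.0,
    "weight_kg": 83.3,
    "heart_rate_bpm": 65.5,
    "bsa_m2": 2.0,
    "lbw_kg": {Arm.BW: 54.8, Arm.LBW: 55.0, Arm.CO: 54.7},
    "co_l_min": {Arm.BW: 6.8, Arm.LBW: 6.9, Arm.CO: 6.9},
}

#: Printed injection-parameter means (mean, sd) per arm.
DOSING_SUMMARY = {
    "cm_volume_ml": {Arm.BW: (47.5, 17.8), Arm.LBW: (44.7, 13.9), Arm.CO: (42.7, 11.5)},
    "test_bolus_ml": {Arm.BW: (11.2, 4.0), Arm.LBW: (10.3, 2.8), Arm.CO: (9.8, 2.2)},
    "flow_rate_ml_s": {Arm.BW: (5.1, 1.7), Arm.LBW: (4.8, 1.2), Arm.CO: (4.6, 1.0)},
    "idr_gi_s": {Arm.BW: (1.5, 0.5), Arm.LBW: (1.4, 0.4), Arm.CO: (1.4, 0.3)},
    "til_gi": {Arm.BW: (14.3, 5.3), Arm.LBW: (13.4, 4.2), Arm.CO: (12.8, 3.5)},
}

#: Printed per-patient attenuation outcomes (mean, sd) per arm.
ATTENUATION_SUMMARY = {Arm.BW: (423.0, 60.0), Arm.LBW: (404.0, 61.0), Arm.CO: (413.0, 63.0)}

#: Printed per-patient outcome percentages per arm.
OUTCOME_PERCENTS = {
    "in_window": {Arm.BW: 83.9, Arm.LBW: 84.3, Arm.CO: 86.9},
    "diagnostic": {Arm.BW: 95.5, Arm.LBW: 89.8, Arm.CO: 95.3},
    "good_excellent": {Arm.BW: 94.6, Arm.LBW: 86.1, Arm.CO: 90.7},
}

#: Printed pairwise BW-vs-LBW p-values for the proportion outcomes.
PRINTED_P_BW_LBW = {
    "good_excellent": 0.031,
    "in_window": 0.947,
    "diagnostic": 0.102,
}

#: Pooled segments assessed per arm (per-segment analyses).
SEGMENT_N = {Arm.BW: 1599, Arm.LBW: 1556, Arm.CO: 1523}
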