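"""Objective and surrogate-subjective image-quality outcomes.

Per patient: overall intravascular attenuation (mean over the assessable
AHA segments), image noise (mean of the per-segment intravascular sds),
CNR = (vessel - fat) / fat_sd, SNR = vessel / noise, the 325-500 HU optimal
window (>=325 HU diagnostic, >500 HU unnecessarily high), and a rule-based
4-point Likert surrogate standing in for the blinded human reading:
4 = no artifacts and sufficient attenuation, 3 = minimal artifacts,
2 = minor artifacts and/or insufficient but still diagnostic attenuation,
1 = major artifacts and/or low attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable

import numpy as np

from .errors import InvalidInputError
from .imaging import ARTIFACT_SEVERITIES, ROIMeasurementSet

__all__ = [
    "WindowClass",
    "PatientQuality",
    "overall_attenuation",
    "cnr",
    "snr",
    "classify_window",
    "is_diagnostic",
    "likert_surrogate",
    "patient_quality",
    "per_segment_summaries",
    "OPTIMAL_WINDOW_HU",
]

#: Optimal intravascular attenuation window, both bounds inclusive.
OPTIMAL_WINDOW_HU = (325.0, 500.0)


class WindowClass(str, Enum):
    BELOW = "below"
    OPTIMAL = "optimal"
    ABOVE = "above"


@dataclass(frozen=True)
class PatientQuality:
    """Per-patient image-quality outcomes (one row of the outcome table)."""

    patient_id: str
    overall_hu: float
    noise: float
    cnr: float
    snr: float
    window: WindowClass
    in_window: bool
    diagnostic: bool
    likert: int

    def __post_init__(self) -> None:
        if self.in_window and not self.diagnostic:
            raise InvalidInputError("in-window attenuation must be diagnostic")
        if self.likert not in (1, 2, 3, 4):
            raise InvalidInputError(f"Likert score {self.likert} outside 1-4")
        if not (np.isfinite(self.cnr) and np.isfinite(self.snr)):
            raise InvalidInputError("CNR and SNR must be finite")


def overall_attenuation(measurements: ROIMeasurementSet) -> float:
    """Per-patient overall attenuation: the mean vessel HU over all present
    segments."""
    values = [s.vessel_hu for s in measurements.segments]
    if not values:
        raise InvalidInputError("no segments to average")
    return float(np.mean(values))


def cnr(vessel_hu: float, fat_hu: float, fat_sd: float) -> float:
    """Contrast-to-noise ratio: (vessel - fat) / sd(fat)."""
    if fat_sd <= 0:
        raise InvalidInputError("fat ROI sd must be positive")
    return (vessel_hu - fat_hu) / fat_sd


def snr(vessel_hu: float, vessel_sd: float) -> float:
    """Signal-to-noise ratio: vessel / sd(vessel)."""
    if vessel_sd <= 0:
        raise InvalidInputError("vessel ROI sd must be positive")
    return vessel_hu / vessel_sd


def classify_window(hu: float) -> WindowClass:
    """Partition attenuation into below / optimal (325-500 HU) / above."""
    if not np.isfinite(hu):
        raise InvalidInputError("attenuation must be finite")
    lo, hi = OPTIMAL_WINDOW_HU
    if hu < lo:
        return WindowClass.BELOW
    if hu <= hi:
        return WindowClass.OPTIMAL
    return WindowClass.ABOVE


def is_diagnostic(hu: float) -> bool:
    """Diagnostic attenuation: >= 325 HU."""
    return hu >= OPTIMAL_WINDOW_HU[0]


def likert_surrogate(hu: float, artifact_flag: bool, artifact_severity: str) -> int:
    """Rule-based stand-in for the blinded 4-point Likert reading."""
    if artifact_severity not in ARTIFACT_SEVERITIES:
        raise InvalidInputError(f"unknown artifact severity {artifact_severity!r}")
    if artifact_flag and artifact_severity == "none":
        raise InvalidInputError("flagged artifact needs a severity above 'none'")
    sufficient = is_diagnostic(hu)
    if artifact_severity == "major" or (not sufficient and artifact_flag):
        return 1
    if artifact_severity == "minor" or not sufficient:
        return 2
    if artifact_severity == "minimal":
        return 3
    return 4


def patient_quality(measurements: ROIMeasurementSet) -> PatientQuality:
    """All per-patient outcomes from one measurement set.

    Noise is the mean of the per-segment intravascular sds (the
    mean-of-segments convention; a single-ROI convention would differ).
    """
    hu = overall_attenuation(measurements)
    noise = float(np.mean([s.vessel_sd for s in measurements.segments]))
    window = classify_window(hu)
    return PatientQuality(
        patient_id=measurements.patient_id,
        overall_hu=hu,
        noise=noise,
        cnr=cnr(hu, measurements.fat_hu, measurements.fat_sd),
        snr=snr(hu, noise),
        window=window,
        in_window=window is WindowClass.OPTIMAL,
        diagnostic=is_diagnostic(hu),
        likert=likert_surrogate(
            hu, measurements.artifact_flag, measurements.artifact_severity
        ),
    )


def per_segment_summaries(
    measurement_sets: Iterable[ROIMeasurementSet],
) -> dict[str, float]:
    """Pooled per-segment outcome proportions across patients.

    Segments are pooled over all patients; each segment is classified by its
    own vessel HU, with the patient's artifact severity applied to its
    surrogate Likert score. Returns counts and proportions (in percent).
    """
    n_segments = 0
    n_window = 0
    n_diagnostic = 0
    n_good_excellent = 0
    for mset in measurement_sets:
        for seg in mset.segments:
            n_segments += 1
            if classify_window(seg.vessel_hu) is WindowClass.OPTIMAL:
                n_window += 1
            if is_diagnostic(seg.vessel_hu):
                n_diagnostic += 1
            score = likert_surrogate(
                seg.vessel_hu, mset.artifact_flag, mset.artifact_severity
            )
            if score >= 3:
                n_good_excellent += 1
    if n_segments == 0:
        raise InvalidInputError("no segments pooled")
    return {
        "n_segments": n_segments,
        "n_in_window": n_window,
        "n_diagnostic": n_diagnostic,
        "n_good_excellent": n_good_excellent,
        "pct_in_window": 100.0 * n_window / n_segments,
        "pct_diagnostic": 100.0 * n_diagnostic / n_segments,
        "pct_good_excellent": 100.0 * n_good_excellent / n_segments,
    }
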