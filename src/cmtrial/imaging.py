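"""Calibrated coronary attenuation simulator.

No quantitative attenuation response was ever released with the trial data,
so downstream analysis is exercised against an explicit, deliberately simple
surrogate: a patient's noise-free mean intravascular attenuation is

    HU = gain(kV) * IDR / CO_true

with IDR the iodine delivery rate of the prescription (gI/s) and CO_true the
patient's latent cardiac output (L/min). This is the smallest model carrying
the qualitative physiology that motivates personalization: attenuation rises
with iodine delivery, falls with cardiac output (dilution), and rises as
tube voltage drops toward the iodine K-edge. The default gain follows
gain(kV) = g0 * (100/kV)^1.3, the approximate power law of iodine contrast
versus tube voltage; because prescribed flow is itself proportional to kV,
the net kV dependence of simulated attenuation is weak, as intended by the
voltage-adapted dosing scheme.

``calibrate_response`` closes the loop: it rescales the gain and solves for
the between-patient noise so a simulated study arm reproduces a target
group mean and standard deviation of per-patient attenuation. Everything
else (fat ROI statistics, vessel noise, segment counts, artifact rates) is
a documented free parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import SimulatedPatient
from .errors import CalibrationError, ConfigError, InvalidInputError, StateError
from .protocol import ALLOWED_TUBE_VOLTAGES, InjectionPrescription, ScanContext

__all__ = [
    "ResponseModel",
    "SegmentMeasurement",
    "ROIMeasurementSet",
    "ArtifactSeverity",
    "default_response_model",
    "expected_attenuation",
    "simulate_measurements",
    "calibrate_response",
]

#: Artifact severity grades used by the subjective-quality surrogate.
ARTIFACT_SEVERITIES = ("none", "minimal", "minor", "major")


def _default_kv_gain(g0: float = 1465.0, power: float = 1.3) -> dict[int, float]:
    return {kv: g0 * (100.0 / kv) ** power for kv in ALLOWED_TUBE_VOLTAGES}


@dataclass(frozen=True)
class ResponseModel:
    """Parameters of the attenuation surrogate.

    kv_gain          HU per (gI/s per L/min), strictly decreasing in kV.
    patient_noise_sd between-patient additive noise on the mean HU.
    segment_noise_sd within-patient between-segment spread in HU.
    fat_mean/fat_hu_sd        epicardial fat ROI attenuation (~ -90 HU).
    fat_sd_mean/fat_sd_sd     spread of the fat ROI's own sd (~35 HU),
                              the denominator of CNR.
    vessel_noise_mean/sd      intravascular image noise: its patient-level
                              mean and between-patient spread (noise is a
                              habitus/dose property, so it varies mostly
                              between patients).
    vessel_noise_within_sd    residual between-segment spread of the sd.
    segment_count_probs       distribution of assessable segments 12..16
                              (mean ~14.3 of the 17 AHA segments).
    artifact_probability      chance a scan shows any artifact.
    artifact_severity_probs   (minimal, minor, major) split given an artifact.
    calibrated       set by calibrate_response; simulation requires it.
    """

    kv_gain: Mapping[int, float] = field(default_factory=_default_kv_gain)
    patient_noise_sd: float = 25.0
    segment_noise_sd: float = 55.0
    fat_mean: float = -90.0
    fat_hu_sd: float = 10.0
    fat_sd_mean: float = 35.0
    fat_sd_sd: float = 5.0
    vessel_noise_mean: float = 39.0
    vessel_noise_sd: float = 8.0
    vessel_noise_within_sd: float = 4.0
    segment_count_probs: Sequence[float] = (0.07, 0.16, 0.30, 0.34, 0.13)
    artifact_probability: float = 0.03
    artifact_severity_probs: Sequence[float] = (0.50, 0.35, 0.15)
    calibrated: bool = False

    def __post_init__(self) -> None:
        for name in ("patient_noise_sd", "segment_noise_sd", "fat_hu_sd",
                     "fat_sd_sd", "vessel_noise_sd", "vessel_noise_within_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        kvs = sorted(self.kv_gain)
        gains = [self.kv_gain[k] for k in kvs]
        if any(b >= a for a, b in zip(gains, gains[1:])) or any(
            g <= 0 for g in gains
        ):
            raise ConfigError("kv_gain must be positive and strictly decreasing in kV")
        if abs(sum(self.segment_count_probs) - 1.0) > 1e-9 or len(
            self.segment_count_probs
        ) != 5:
            raise ConfigError("segment_count_probs must be 5 probabilities over 12..16")
        if not 0 <= self.artifact_probability <= 1:
            raise ConfigError("artifact_probability must lie in [0, 1]")
        if abs(sum(self.artifact_severity_probs) - 1.0) > 1e-9:
            raise ConfigError("artifact_severity_probs must sum to 1")

    @property
    def mean_segment_count(self) -> float:
        return float(np.dot(self.segment_count_probs, np.arange(12, 17)))


def default_response_model(**overrides) -> ResponseModel:
    """An uncalibrated model with the documented defaults."""
    return ResponseModel(**overrides)


@dataclass(frozen=True)
class SegmentMeasurement:
    """One coronary segment's ROI readout."""

    label: int  # AHA segment number, 1..17
    vessel_hu: float
    vessel_sd: float


@dataclass(frozen=True)
class ROIMeasurementSet:
    """All ROI measurements for one scanned patient."""

    patient_id: str
    segments: tuple[SegmentMeasurement, ...]
    fat_hu: float
    fat_sd: float
    artifact_flag: bool
    artifact_severity: str  # one of ARTIFACT_SEVERITIES

    def __post_init__(self) -> None:
        if not self.segments:
            raise InvalidInputError("a measurement set needs at least one segment")
        labels = [s.label for s in self.segments]
        if len(set(labels)) != len(labels):
            raise InvalidInputError("duplicate AHA segment labels")
        if self.fat_sd <= 0 or any(s.vessel_sd <= 0 for s in self.segments):
            raise InvalidInputError("ROI standard deviations must be positive")
        if self.artifact_severity not in ARTIFACT_SEVERITIES:
            raise InvalidInputError(
                f"unknown artifact severity {self.artifact_severity!r}"
            )


def expected_attenuation(
    model: ResponseModel, tube_voltage: int, idr: float, true_co: float
) -> float:
    """Noise-free mean intravascular attenuation, gain(kV) * IDR / CO."""
    if true_co <= 0:
        raise InvalidInputError("true cardiac output must be positive")
    try:
        gain = model.kv_gain[tube_voltage]
    except KeyError as exc:
        raise InvalidInputError(f"no gain for {tube_voltage} kV") from exc
    return gain * idr / true_co


def simulate_measurements(
    patient: SimulatedPatient,
    prescription: InjectionPrescription,
    scan_context: ScanContext,
    model: ResponseModel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ROIMeasurementSet:
    """Draw one patient's per-segment ROI measurements.

    Deterministic given ``seed`` (or a caller-managed ``rng``). Requires a
    calibrated model: simulating from an uncalibrated response silently
    produces attenuations on an arbitrary scale, so it is a state error.
    """
    if not model.calibrated:
        raise StateError(
            "response model is not calibrated; run calibrate_response first "
            "or construct the model with calibrated=True deliberately"
        )
    if prescription.patient_id != patient.profile.id:
        raise InvalidInputError(
            f"prescription for {prescription.patient_id} does not match "
            f"patient {patient.profile.id}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    mean_hu = expected_attenuation(
        model, scan_context.tube_voltage, prescription.idr, patient.true_co
    )
    mean_hu += rng.normal(0.0, model.patient_noise_sd) if model.patient_noise_sd else 0.0

    n_seg = int(rng.choice(np.arange(12, 17), p=list(model.segment_count_probs)))
    labels = np.sort(rng.choice(np.arange(1, 18), size=n_seg, replace=False))
    seg_offsets = (
        rng.normal(0.0, model.segment_noise_sd, n_seg)
        if model.segment_noise_sd
        else np.zeros(n_seg)
    )
    patient_noise_level = float(
        _positive_normal(rng, 1, model.vessel_noise_mean, model.vessel_noise_sd)[0]
    )
    vessel_sds = _positive_normal(
        rng, n_seg, patient_noise_level, model.vessel_noise_within_sd
    )
    fat_hu = float(rng.normal(model.fat_mean, model.fat_hu_sd))
    fat_sd = float(_positive_normal(rng, 1, model.fat_sd_mean, model.fat_sd_sd)[0])

    artifact = bool(rng.random() < model.artifact_probability)
    if artifact:
        severity = str(
            rng.choice(ARTIFACT_SEVERITIES[1:], p=list(model.artifact_severity_probs))
        )
    else:
        severity = "none"

    segments = tuple(
        SegmentMeasurement(
            label=int(lab), vessel_hu=float(mean_hu + off), vessel_sd=float(sd)
        )
        for lab, off, sd in zip(labels, seg_offsets, vessel_sds)
    )
    return ROIMeasurementSet(
        patient_id=patient.profile.id,
        segments=segments,
        fat_hu=fat_hu,
        fat_sd=fat_sd,
        artifact_flag=artifact,
        artifact_severity=severity,
    )


def _positive_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, floor: float = 1.0
) -> np.ndarray:
    """Normal draws clipped away from zero (ROI sds must stay positive)."""
    if sd == 0:
        return np.full(n, max(mean, floor))
    return np.maximum(rng.normal(mean, sd, n), floor)


def _overall_hu_sample(
    cohort: Sequence[SimulatedPatient],
    prescriptions: Sequence[InjectionPrescription],
    contexts: Sequence[ScanContext],
    model: ResponseModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised per-patient overall attenuation (mean over segments) under
    the response model; used by the calibration loop."""
    n = len(cohort)
    gains = np.array([model.kv_gain[c.tube_voltage] for c in contexts])
    idrs = np.array([p.idr for p in prescriptions])
    cos = np.array([p.true_co for p in cohort])
    mean_hu = gains * idrs / cos
    mean_hu = mean_hu + rng.normal(0.0, model.patient_noise_sd, n)
    n_segs = rng.choice(np.arange(12, 17), size=n, p=list(model.segment_count_probs))
    seg_noise = rng.normal(0.0, 1.0, n) * model.segment_noise_sd / np.sqrt(n_segs)
    return mean_hu + seg_noise


def calibrate_response(
    model: ResponseModel,
    cohort: Sequence[SimulatedPatient],
    prescriptions: Sequence[InjectionPrescription],
    contexts: Sequence[ScanContext],
    target_mean: float,
    target_sd: float,
    seed: int = 0,
    tol_mean: float = 5.0,
    tol_sd: float = 5.0,
    max_iter: int = 10,
) -> ResponseModel:
    """Scale ``kv_gain`` and solve ``patient_noise_sd`` to hit group targets.

    The pilot arm (cohort + matching prescriptions + scan contexts) is
    simulated repeatedly: the gain map is rescaled multiplicatively toward
    the target mean (the response is linear in the gain) and the
    between-patient noise is set from the variance budget left over once the
    dosing-driven signal spread and the segment-averaging term are accounted
    for. Deterministic given ``seed``; raises CalibrationError with
    diagnostics if the targets are not met within ``max_iter`` rounds, e.g.
    when the signal spread alone already exceeds ``target_sd + tol_sd``.
    """
    if not (len(cohort) == len(prescriptions) == len(contexts)):
        raise InvalidInputError("cohort, prescriptions and contexts must align")
    if len(cohort) < 2:
        raise InvalidInputError("calibration needs at least 2 patients")
    if target_mean <= 0 or target_sd < 0:
        raise InvalidInputError("targets must be positive (sd may be 0)")

    ss = np.random.SeedSequence([int(seed), 0x10D1])
    current = replace(model, calibrated=False)

    # Noise-free signal moments (exact, no Monte Carlo needed).
    gains = np.array([current.kv_gain[c.tube_voltage] for c in contexts])
    signal = gains * np.array([p.idr for p in prescriptions]) / np.array(
        [p.true_co for p in cohort]
    )
    m0, s0 = float(np.mean(signal)), float(np.std(signal, ddof=1))
    scale = target_mean / m0
    kv_gain = {k: v * scale for k, v in current.kv_gain.items()}
    signal_sd = s0 * scale
    seg_var = float(
        np.dot(current.segment_count_probs, 1.0 / np.arange(12, 17))
    ) * current.segment_noise_sd**2
    residual = target_sd**2 - signal_sd**2 - seg_var
    patient_noise_sd = math.sqrt(residual) if residual > 0 else 0.0
    current = replace(
        current, kv_gain=kv_gain, patient_noise_sd=patient_noise_sd, calibrated=True
    )

    achieved = (math.nan, math.nan)
    for iteration in range(max_iter):
        rng = np.random.default_rng(ss.spawn(1)[0])
        sample = _overall_hu_sample(cohort, prescriptions, contexts, current, rng)
        m, s = float(np.mean(sample)), float(np.std(sample, ddof=1))
        achieved = (m, s)
        if abs(m - target_mean) <= tol_mean and abs(s - target_sd) <= tol_sd:
            return current
        # Mean correction: rescale gains; noise terms have mean zero.
        kv_gain = {k: v * target_mean / m for k, v in current.kv_gain.items()}
        # SD correction on the patient-noise component.
        other_var = max(s**2 - current.patient_noise_sd**2, 0.0)
        residual = target_sd**2 - other_var
        patient_noise_sd = math.sqrt(residual) if residual > 0 else 0.0
        current = replace(
            current, kv_gain=kv_gain, patient_noise_sd=patient_noise_sd
        )

    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations: achieved "
        f"mean/sd {achieved[0]:.1f}/{achieved[1]:.1f} vs targets "
        f"{target_mean}/{target_sd} (+/-{tol_mean}/{tol_sd}); the irreducible "
        f"signal spread is {signal_sd:.1f} HU"
    )
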