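"""Synthetic trial cohort: virtual adults referred for coronary CTA.

The generator draws demographics and vitals from truncated normal marginals
parameterized by the original cohort's summary statistics (n=327 adults,
weight 83.3 +/- 15.9 kg, height 173 +/- 10 cm, age ~60 +/- 10.6 y, heart
rate 65.5 +/- 13.1 bpm, 51.4% women). Height carries a sex offset and a
configurable height-weight correlation, both folded into the marginal
moments so pooled means/sds still match the configured values. Each patient
also carries a latent "true" cardiac output - the Katori estimate times a
mean-one lognormal multiplier - so formula-based personalization is an
imperfect proxy of physiology, and a deviation flag modelling non-adherence
to the assigned injection protocol (41/327 in the original trial).

Scan logistics are emulated too: heart rate selects the acquisition mode
(<=70 bpm high-pitch flash, 70-90 step-and-shoot, >90 helical) and a
deterministic BMI-quantile rule stands in for the scanner's automated
tube-voltage selection, calibrated to the observed kV usage shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import ConfigError, InvalidInputError
from .protocol import (
    PatientProfile,
    ScanProtocol,
    Sex,
    derive_bsa,
    derive_co_katori,
)

__all__ = [
    "CohortSpec",
    "SimulatedPatient",
    "generate_cohort",
    "assign_scan_protocol",
    "assign_tube_voltage",
    "kv_cutpoints",
    "KV_LEVELS",
    "KV_TARGET_SHARES",
]

# Truncation bounds (the type invariants of PatientProfile, plus plausible
# physiology for heart rate and age).
AGE_BOUNDS = (18.0, 100.0)
HEIGHT_BOUNDS = (100.0, 250.0)
WEIGHT_BOUNDS = (30.0, 250.0)
HEART_RATE_BOUNDS = (25.0, 220.0)

#: kV levels produced by the tube-voltage surrogate. 110 kV is omitted: the
#: automated selection never chose it in the original cohort.
KV_LEVELS = (70, 80, 90, 100, 120)

#: Target share of scans at each kV (observed usage, pooled over arms).
KV_TARGET_SHARES = {
    70: 131 / 327,
    80: 126 / 327,
    90: 33 / 327,
    100: 16 / 327,
    120: 21 / 327,
}


@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters of the virtual cohort.

    Means/sds are in years, cm, kg and bpm. ``sex_height_offset_cm`` is half
    the male-female mean height gap; ``co_lognormal_sigma`` is the log-sd of
    the latent cardiac-output multiplier (0 makes the Katori formula exact);
    ``deviation_probability`` is the chance a patient's injection deviates
    from the assigned protocol.

    Heart rate is right-skewed in practice (beta blockade pushes most
    patients to <=70 bpm while a small subgroup - atrial fibrillation and
    other persistent tachycardias - stays high): it is drawn as a mixture
    of a lognormal majority and a ``tachy_fraction`` normal component at
    ``tachy_mean`` bpm, with the majority's parameters solved so the pooled
    mean and sd equal ``heart_rate_mean``/``heart_rate_sd`` exactly.
    """

    n: int = 327
    age_mean: float = 60.0
    age_sd: float = 10.6
    height_mean: float = 173.0
    height_sd: float = 10.0
    weight_mean: float = 83.3
    weight_sd: float = 15.9
    heart_rate_mean: float = 65.5
    heart_rate_sd: float = 13.1
    tachy_fraction: float = 0.05
    tachy_mean: float = 95.0
    tachy_sd: float = 10.0
    sex_fraction_female: float = 0.514
    height_weight_corr: float = 0.4
    sex_height_offset_cm: float = 6.5
    co_lognormal_sigma: float = 0.10
    deviation_probability: float = 41 / 327
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ConfigError("cohort size n must be positive")
        for name, sd in [
            ("age_sd", self.age_sd),
            ("height_sd", self.height_sd),
            ("weight_sd", self.weight_sd),
            ("heart_rate_sd", self.heart_rate_sd),
        ]:
            if sd < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name, p in [
            ("sex_fraction_female", self.sex_fraction_female),
            ("deviation_probability", self.deviation_probability),
            ("tachy_fraction", self.tachy_fraction),
        ]:
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not -1 < self.height_weight_corr < 1:
            raise ConfigError("height_weight_corr must lie in (-1, 1)")
        for name, mean, (lo, hi) in [
            ("age_mean", self.age_mean, AGE_BOUNDS),
            ("height_mean", self.height_mean, HEIGHT_BOUNDS),
            ("weight_mean", self.weight_mean, WEIGHT_BOUNDS),
            ("heart_rate_mean", self.heart_rate_mean, HEART_RATE_BOUNDS),
        ]:
            if not lo < mean < hi:
                raise ConfigError(
                    f"{name}={mean} lies outside the truncation bounds ({lo}, {hi}); "
                    "the truncated distribution is infeasible"
                )


@dataclass(frozen=True)
class SimulatedPatient:
    """A virtual patient: profile plus latent physiology and adherence."""

    profile: PatientProfile
    true_co: float  # L/min, latent physiologic cardiac output
    deviation_flag: bool


def _sex_height_params(spec: CohortSpec) -> tuple[float, float, float]:
    """(male mean, female mean, within-sex sd) for height.

    The offsets are weighted so the pooled mean equals ``height_mean`` and
    the within-sex sd is shrunk so the pooled sd equals ``height_sd``.
    """
    p_f = spec.sex_fraction_female
    p_m = 1.0 - p_f
    delta_m = 2.0 * spec.sex_height_offset_cm * p_f
    delta_f = -2.0 * spec.sex_height_offset_cm * p_m
    between_var = 4.0 * p_f * p_m * spec.sex_height_offset_cm**2
    within_var = spec.height_sd**2 - between_var
    if within_var < 0:
        raise ConfigError(
            "sex_height_offset_cm implies more between-sex height variance "
            f"({between_var:.1f}) than the total height variance ({spec.height_sd**2:.1f})"
        )
    return spec.height_mean + delta_m, spec.height_mean + delta_f, math.sqrt(within_var)


def _heart_rate_mixture_params(spec: CohortSpec) -> tuple[float, float]:
    """(mu, sigma) of the majority lognormal component of heart rate.

    Solved so the mixture with the tachycardic normal component has pooled
    mean ``heart_rate_mean`` and sd ``heart_rate_sd`` exactly.
    """
    w = spec.tachy_fraction
    m, s = spec.heart_rate_mean, spec.heart_rate_sd
    base_mean = (m - w * spec.tachy_mean) / (1.0 - w)
    second_moment = s**2 + m**2
    base_var = (
        second_moment - w * (spec.tachy_sd**2 + spec.tachy_mean**2)
    ) / (1.0 - w) - base_mean**2
    if base_mean <= 0 or base_var <= 0:
        raise ConfigError(
            "heart-rate mixture infeasible: the tachycardic component "
            "already exceeds the pooled mean or variance"
        )
    sigma2 = math.log1p(base_var / base_mean**2)
    mu = math.log(base_mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def _sample_heart_rates(
    rng: np.random.Generator, n: int, spec: CohortSpec
) -> np.ndarray:
    if spec.heart_rate_sd == 0:
        return np.full(n, spec.heart_rate_mean)
    mu, sigma = _heart_rate_mixture_params(spec)
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(100):
        if todo.size == 0:
            return out
        m = todo.size
        tachy = rng.random(m) < spec.tachy_fraction
        hr = np.where(
            tachy,
            rng.normal(spec.tachy_mean, spec.tachy_sd, m),
            rng.lognormal(mu, sigma, m),
        )
        ok = (hr > HEART_RATE_BOUNDS[0]) & (hr < HEART_RATE_BOUNDS[1])
        out[todo[ok]] = hr[ok]
        todo = todo[~ok]
    raise ConfigError("heart-rate truncation rejected too many draws")


def _rejection_truncnorm_pair(
    rng: np.random.Generator,
    n: int,
    h_means: np.ndarray,
    h_sd: float,
    w_mean: float,
    w_sd: float,
    corr: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlated (height, weight) draws truncated to their bounds.

    Truncation is by rejection; at the default parameters the bounds sit
    several sds out, so acceptance is essentially 1.
    """
    heights = np.empty(n)
    weights = np.empty(n)
    todo = np.arange(n)
    for _ in range(100):
        m = todo.size
        if m == 0:
            return heights, weights
        z_h = rng.standard_normal(m)
        z_w = corr * z_h + math.sqrt(1.0 - corr**2) * rng.standard_normal(m)
        h = h_means[todo] + h_sd * z_h
        w = w_mean + w_sd * z_w
        ok = (
            (h > HEIGHT_BOUNDS[0]) & (h < HEIGHT_BOUNDS[1])
            & (w > WEIGHT_BOUNDS[0]) & (w < WEIGHT_BOUNDS[1])
        )
        heights[todo[ok]] = h[ok]
        weights[todo[ok]] = w[ok]
        todo = todo[~ok]
    raise ConfigError("height/weight truncation rejected too many draws")


def _truncnorm(
    rng: np.random.Generator, n: int, mean: float, sd: float, bounds: tuple[float, float]
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(n)
    todo = np.arange(n)
    for _ in range(100):
        if todo.size == 0:
            return out
        x = rng.normal(mean, sd, todo.size)
        ok = (x > bounds[0]) & (x < bounds[1])
        out[todo[ok]] = x[ok]
        todo = todo[~ok]
    raise ConfigError(f"truncation at {bounds} rejected too many draws")


def generate_cohort(
    spec: CohortSpec, seed: Optional[int] = None
) -> list[SimulatedPatient]:
    """Draw ``spec.n`` virtual patients, reproducibly under a seed.

    ``seed`` overrides ``spec.seed``; one of the two must be set for a
    reproducible cohort (both None falls back to OS entropy).
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n = spec.n

    female = rng.random(n) < spec.sex_fraction_female
    mean_m, mean_f, h_sd = _sex_height_params(spec)
    h_means = np.where(female, mean_f, mean_m)
    if spec.height_sd == 0 and spec.weight_sd == 0:
        heights = h_means.copy()
        weights = np.full(n, spec.weight_mean)
    else:
        heights, weights = _rejection_truncnorm_pair(
            rng, n, h_means, h_sd, spec.weight_mean, spec.weight_sd,
            spec.height_weight_corr,
        )
    ages = np.rint(_truncnorm(rng, n, spec.age_mean, spec.age_sd, AGE_BOUNDS))
    ages = np.clip(ages, 18, None).astype(int)
    heart_rates = _sample_heart_rates(rng, n, spec)
    if spec.co_lognormal_sigma > 0:
        sigma = spec.co_lognormal_sigma
        co_mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    else:
        co_mult = np.ones(n)
    deviations = rng.random(n) < spec.deviation_probability

    width = max(4, len(str(n)))
    patients = []
    for i in range(n):
        profile = PatientProfile(
            id=f"P{i + 1:0{width}d}",
            sex=Sex.FEMALE if female[i] else Sex.MALE,
            age=int(ages[i]),
            height=float(heights[i]),
            weight=float(weights[i]),
            heart_rate=float(heart_rates[i]),
        )
        bsa = derive_bsa(profile.weight, profile.height)
        katori = derive_co_katori(profile.age, bsa)
        patients.append(
            SimulatedPatient(
                profile=profile,
                true_co=float(katori * co_mult[i]),
                deviation_flag=bool(deviations[i]),
            )
        )
    return patients


def assign_scan_protocol(heart_rate: float) -> ScanProtocol:
    """Acquisition mode from heart rate: <=70 bpm flash, (70, 90] adaptive
    sequence, >90 helical."""
    if heart_rate is None or heart_rate <= 0:
        raise InvalidInputError("heart rate must be positive")
    if heart_rate <= 70:
        return ScanProtocol.FLASH
    if heart_rate <= 90:
        return ScanProtocol.ADAPTIVE_SEQUENCE
    return ScanProtocol.HELICAL


# Internal seed for the quantile-calibration sample; fixed so the cutpoints
# are a deterministic function of the CohortSpec alone.
_CUTPOINT_SEED = 20170401
_CUTPOINT_SAMPLE = 50_000


def kv_cutpoints(
    spec: CohortSpec,
    shares: Optional[dict[int, float]] = None,
    sample_size: int = _CUTPOINT_SAMPLE,
) -> np.ndarray:
    """BMI cutpoints making the kV surrogate hit the target usage shares.

    The cutpoints are the BMI quantiles of a large deterministic sample from
    ``spec`` at the cumulative shares, so at matching cohort parameters the
    generated kV frequencies approximate the targets.
    """
    shares = dict(KV_TARGET_SHARES if shares is None else shares)
    if sorted(shares) != sorted(set(shares)) or any(v < 0 for v in shares.values()):
        raise ConfigError("kV shares must be non-negative")
    levels = sorted(shares)
    total = sum(shares.values())
    cum = np.cumsum([shares[k] / total for k in levels])[:-1]
    calib_spec = replace(spec, n=sample_size, seed=_CUTPOINT_SEED)
    rng = np.random.default_rng(_CUTPOINT_SEED)
    female = rng.random(sample_size) < calib_spec.sex_fraction_female
    mean_m, mean_f, h_sd = _sex_height_params(calib_spec)
    h_means = np.where(female, mean_f, mean_m)
    heights, weights = _rejection_truncnorm_pair(
        rng, sample_size, h_means, h_sd,
        calib_spec.weight_mean, calib_spec.weight_sd, calib_spec.height_weight_corr,
    )
    bmi = weights / (heights / 100.0) ** 2
    return np.quantile(bmi, cum)


def assign_tube_voltage(
    patient: PatientProfile,
    cutpoints: Optional[np.ndarray] = None,
    spec: Optional[CohortSpec] = None,
) -> int:
    """Surrogate automated tube-voltage selection: a monotone BMI rule.

    Heavier habitus (higher BMI) never receives a lower kV than a lighter
    one. Pass precomputed ``cutpoints`` when assigning many patients;
    otherwise they are derived from ``spec`` (default spec if omitted).
    """
    if cutpoints is None:
        cutpoints = kv_cutpoints(spec if spec is not None else CohortSpec())
    idx = int(np.searchsorted(cutpoints, patient.bmi, side="right"))
    return KV_LEVELS[idx]
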