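"""Personalized contrast-media (CM) injection prescriptions for coronary CTA.

The engine turns one patient's anthropometry into a tailored injection: a
flow rate proportional to tube voltage and to one of three body parameters
(total body weight, Hume lean body weight, or an adapted Katori cardiac
output), fixed injection times per scan protocol, and the derived bolus
volumes, iodine delivery rate (IDR, gI/s) and total iodine load (TIL, gI).
All arithmetic is exact/unrounded; one-decimal rounding is applied only when
comparing against printed summary tables (see :func:`round_half_away`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .errors import (
    ContractError,
    ImplausibleInputError,
    InvalidInputError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Arm",
    "ScanProtocol",
    "ALLOWED_TUBE_VOLTAGES",
    "PatientProfile",
    "DerivedBody",
    "ScanContext",
    "ContrastAgent",
    "InjectionPrescription",
    "derive_lbw_hume",
    "derive_bsa",
    "derive_co_katori",
    "derive_body",
    "flow_rate",
    "injection_durations",
    "prescribe",
    "round_half_away",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Arm(str, Enum):
    """The three personalization strategies under comparison."""

    BW = "BW"
    LBW = "LBW"
    CO = "CO"


class ScanProtocol(str, Enum):
    """Heart-rate-selected acquisition modes on a dual-source scanner."""

    FLASH = "flash"  # high-pitch prospective
    ADAPTIVE_SEQUENCE = "adaptive_sequence"  # step-and-shoot
    HELICAL = "helical"  # retrospective spiral


#: Tube voltages available to the automated tube-voltage selection.
ALLOWED_TUBE_VOLTAGES = (70, 80, 90, 100, 110, 120)

#: Flow-rate coefficients, mL/s per (kV x body parameter). The body
#: parameter is kg for BW/LBW and L/min for CO.
FLOW_COEFFICIENTS = {
    Arm.BW: 0.0007976,
    Arm.LBW: 0.001101,
    Arm.CO: 0.008916,
}

#: Fixed injection times in seconds: test bolus always 2 s; main bolus
#: matches the scan time of the selected protocol.
TEST_BOLUS_DURATION_S = 2.0
MAIN_BOLUS_DURATION_S = {
    ScanProtocol.FLASH: 8.0,
    ScanProtocol.ADAPTIVE_SEQUENCE: 10.0,
    ScanProtocol.HELICAL: 10.0,
}

#: Flow rates outside this window are logged as implausible but not rejected
#: (in practice such prescriptions are adjusted to the needle at the table).
PLAUSIBLE_FLOW_WINDOW = (1.0, 12.0)


@dataclass(frozen=True)
class PatientProfile:
    """Demographics and vitals driving dosing and stratification.

    Units: age in years (integer, adults only), height in cm, weight in kg,
    heart rate in beats per minute.
    """

    id: str
    sex: Sex
    age: int
    height: float
    weight: float
    heart_rate: float

    def __post_init__(self) -> None:
        if self.age < 18:
            raise InvalidInputError(f"patient {self.id}: age {self.age} < 18")
        if not 100 < self.height < 250:
            raise InvalidInputError(
                f"patient {self.id}: height {self.height} cm outside (100, 250)"
            )
        if not 30 < self.weight < 250:
            raise InvalidInputError(
                f"patient {self.id}: weight {self.weight} kg outside (30, 250)"
            )
        if self.heart_rate <= 0:
            raise InvalidInputError(f"patient {self.id}: non-positive heart rate")

    @property
    def bmi(self) -> float:
        """Body mass index in kg/m^2."""
        return self.weight / (self.height / 100.0) ** 2


@dataclass(frozen=True)
class DerivedBody:
    """Formula-derived body parameters: lean body weight (kg), body surface
    area (m^2) and cardiac output (L/min)."""

    lbw: float
    bsa: float
    co: float

    def __post_init__(self) -> None:
        if not self.lbw > 0:
            raise ImplausibleInputError(f"non-positive lean body weight {self.lbw}")
        if not 1.0 < self.bsa < 3.5:
            raise ImplausibleInputError(f"BSA {self.bsa} m^2 outside (1.0, 3.5)")
        if not self.co > 0:
            raise ImplausibleInputError(f"non-positive cardiac output {self.co}")


@dataclass(frozen=True)
class ScanContext:
    """Acquisition mode and tube voltage chosen for one scan."""

    scan_protocol: ScanProtocol
    tube_voltage: int

    def __post_init__(self) -> None:
        if self.tube_voltage not in ALLOWED_TUBE_VOLTAGES:
            raise InvalidInputError(
                f"tube voltage {self.tube_voltage} kV not in {ALLOWED_TUBE_VOLTAGES}"
            )


@dataclass(frozen=True)
class ContrastAgent:
    """Contrast agent and injector constraints.

    ``iodine_concentration`` is in grams of iodine per mL (0.3 gI/mL is the
    conventional 300 mgI/mL agent). Flow rates above ``high_flow_threshold``
    require a reinforced high-flow needle rated to ``pressure_limit`` psi.
    """

    iodine_concentration: float = 0.3
    pressure_limit: float = 325.0
    high_flow_threshold: float = 7.0

    def __post_init__(self) -> None:
        if self.iodine_concentration <= 0:
            raise InvalidInputError("iodine concentration must be positive")


@dataclass(frozen=True)
class InjectionPrescription:
    """A complete injection order for one patient under one arm."""

    patient_id: str
    arm: Arm
    flow_rate: float  # mL/s
    test_bolus_volume: float  # mL
    main_bolus_volume: float  # mL
    test_duration: float  # s
    main_duration: float  # s
    idr: float  # gI/s
    til: float  # gI
    requires_high_flow_needle: bool


def derive_lbw_hume(sex: Sex, weight: float, height: float) -> float:
    """Lean body weight (kg) by the Hume equations.

    male:   0.32810*W + 0.33929*L - 29.5336
    female: 0.29569*W + 0.41813*L - 43.2933

    with W the body weight in kg and L the body length in cm.
    """
    if weight is None or height is None or weight <= 0 or height <= 0:
        raise InvalidInputError("weight and height must be positive")
    sex = Sex(sex)
    if sex is Sex.MALE:
        lbw = 0.32810 * weight + 0.33929 * height - 29.5336
    else:
        lbw = 0.29569 * weight + 0.41813 * height - 43.2933
    if lbw <= 0:
        raise ImplausibleInputError(
            f"Hume LBW {lbw:.2f} kg <= 0 for sex={sex.value}, W={weight}, L={height}"
        )
    return lbw


def derive_bsa(weight: float, height: float, method: str = "dubois") -> float:
    """Body surface area (m^2) from weight (kg) and height (cm).

    ``method`` selects the estimator: "dubois" (default),
    0.007184 * W^0.425 * H^0.725, or "mosteller", sqrt(W*H/3600).
    """
    if weight <= 0 or height <= 0:
        raise InvalidInputError("weight and height must be positive")
    if method == "dubois":
        return 0.007184 * weight**0.425 * height**0.725
    if method == "mosteller":
        return math.sqrt(weight * height / 3600.0)
    raise InvalidInputError(f"unknown BSA method {method!r}")


def derive_co_katori(age: float, bsa: float) -> float:
    """Cardiac output (L/min) by the adapted Katori regression.

    CO = (4.874 - 0.023*age) * BSA, age in years, BSA in m^2.
    """
    if bsa <= 0:
        raise InvalidInputError("BSA must be positive")
    if age < 18:
        raise InvalidInputError("adults only (age >= 18)")
    cardiac_index = 4.874 - 0.023 * age
    if cardiac_index <= 0:
        raise ImplausibleInputError(f"age {age} puts the Katori cardiac index <= 0")
    return cardiac_index * bsa


def derive_body(patient: PatientProfile, bsa_method: str = "dubois") -> DerivedBody:
    """All formula-derived body parameters for one patient."""
    lbw = derive_lbw_hume(patient.sex, patient.weight, patient.height)
    bsa = derive_bsa(patient.weight, patient.height, method=bsa_method)
    co = derive_co_katori(patient.age, bsa)
    return DerivedBody(lbw=lbw, bsa=bsa, co=co)


def flow_rate(
    arm: Arm,
    tube_voltage: int,
    *,
    weight: Optional[float] = None,
    lbw: Optional[float] = None,
    co: Optional[float] = None,
) -> float:
    """Tailored flow rate (mL/s) for one arm at one tube voltage.

    Exactly the body parameter matching the arm must be supplied: ``weight``
    (kg) for BW, ``lbw`` (kg) for LBW, ``co`` (L/min) for CO. Supplying a
    mismatched combination raises :class:`ContractError`.
    """
    arm = Arm(arm)
    if tube_voltage not in ALLOWED_TUBE_VOLTAGES:
        raise InvalidInputError(f"tube voltage {tube_voltage} kV not allowed")
    supplied = {"weight": weight, "lbw": lbw, "co": co}
    expected = {Arm.BW: "weight", Arm.LBW: "lbw", Arm.CO: "co"}[arm]
    extra = [k for k, v in supplied.items() if v is not None and k != expected]
    if extra or supplied[expected] is None:
        raise ContractError(
            f"arm {arm.value} requires the {expected!r} parameter alone, "
            f"got {[k for k, v in supplied.items() if v is not None]}"
        )
    value = supplied[expected]
    if value <= 0:
        raise InvalidInputError(f"{expected} must be positive")
    return FLOW_COEFFICIENTS[arm] * tube_voltage * value


def injection_durations(scan_protocol: ScanProtocol) -> tuple[float, float]:
    """(test, main) injection times in seconds for a scan protocol.

    The test bolus is always 2 s; the main bolus runs 8 s for the high-pitch
    flash mode and 10 s for adaptive-sequence and helical modes.
    """
    try:
        protocol = ScanProtocol(scan_protocol)
    except ValueError as exc:
        raise InvalidInputError(f"unknown scan protocol {scan_protocol!r}") from exc
    return TEST_BOLUS_DURATION_S, MAIN_BOLUS_DURATION_S[protocol]


def prescribe(
    patient: PatientProfile,
    scan_context: ScanContext,
    arm: Arm,
    agent: ContrastAgent = ContrastAgent(),
    bsa_method: str = "dubois",
    derived: Optional[DerivedBody] = None,
) -> InjectionPrescription:
    """Compose the full injection prescription for one patient.

    Pass ``derived`` to reuse precomputed body parameters; otherwise they are
    derived here. Flow rates outside the 1-12 mL/s plausibility window are
    logged as warnings, mirroring how out-of-range orders are handled at the
    scanner (adjusted, not rejected).
    """
    arm = Arm(arm)
    if derived is None:
        derived = derive_body(patient, bsa_method=bsa_method)
    if arm is Arm.BW:
        flow = flow_rate(arm, scan_context.tube_voltage, weight=patient.weight)
    elif arm is Arm.LBW:
        flow = flow_rate(arm, scan_context.tube_voltage, lbw=derived.lbw)
    else:
        flow = flow_rate(arm, scan_context.tube_voltage, co=derived.co)

    lo, hi = PLAUSIBLE_FLOW_WINDOW
    if not lo <= flow <= hi:
        logger.warning(
            "patient %s: flow rate %.2f mL/s outside plausible window (%g, %g)",
            patient.id,
            flow,
            lo,
            hi,
        )

    test_s, main_s = injection_durations(scan_context.scan_protocol)
    test_volume = flow * test_s
    main_volume = flow * main_s
    return InjectionPrescription(
        patient_id=patient.id,
        arm=arm,
        flow_rate=flow,
        test_bolus_volume=test_volume,
        main_bolus_volume=main_volume,
        test_duration=test_s,
        main_duration=main_s,
        idr=flow * agent.iodine_concentration,
        til=main_volume * agent.iodine_concentration,
        requires_high_flow_needle=flow > agent.high_flow_threshold,
    )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of printed clinical tables.

    Python's built-in ``round`` is banker's rounding; summary tables round
    14.25 to 14.3, so table comparisons go through this helper.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
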