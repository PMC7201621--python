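"""Stratified 1:1:1 randomization with variable random permuted blocks.

Patients are stratified on age (<50, 50-69, >=70 years) and weight
(<60, 60-69, 70-90, >90 kg), giving 12 strata. Each stratum runs its own
block schedule: block sizes are drawn at random from a configured set of
multiples of 3 and each block is a random permutation holding every arm
size/3 times, so allocation stays concealed while per-stratum imbalance is
bounded by the block structure.

Boundary closure: the printed bands leave 69-70 formally unassigned, so the
bands are taken half-open with age 70 in the oldest band and weight 70 kg
(and exactly 90 kg) in the 70-90 band, making stratification total.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import ConfigError, InvalidInputError
from .protocol import Arm, PatientProfile

__all__ = [
    "AgeBand",
    "WeightBand",
    "Stratum",
    "Allocation",
    "ALL_STRATA",
    "stratum_of",
    "randomize",
]


class AgeBand(str, Enum):
    UNDER50 = "under50"
    FROM50TO69 = "50to69"
    OVER70 = "70plus"


class WeightBand(str, Enum):
    UNDER60 = "under60"
    FROM60TO69 = "60to69"
    FROM70TO90 = "70to90"
    OVER90 = "over90"


@dataclass(frozen=True)
class Stratum:
    age_band: AgeBand
    weight_band: WeightBand

    @property
    def label(self) -> str:
        return f"{self.age_band.value}/{self.weight_band.value}"


#: The 12 strata in a fixed canonical order (drives seed fan-out).
ALL_STRATA = tuple(
    Stratum(a, w) for a in AgeBand for w in WeightBand
)


@dataclass(frozen=True)
class Allocation:
    """One patient's arm assignment with its block provenance."""

    patient_id: str
    arm: Arm
    stratum: Stratum
    block_index: int
    position_in_block: int
    seed_fingerprint: str


def stratum_of(patient: Union[PatientProfile, tuple[float, float]]) -> Stratum:
    """Map a patient (or an ``(age, weight)`` pair) to its stratum.

    Age bands: [18, 50), [50, 70), [70, inf). Weight bands in kg:
    (0, 60), [60, 70), [70, 90], (90, inf). Raw (unrounded) values are
    banded so the mapping is deterministic for non-integer weights.
    """
    if isinstance(patient, PatientProfile):
        age, weight = patient.age, patient.weight
    else:
        age, weight = patient
    if age is None or weight is None:
        raise InvalidInputError("age and weight are required for stratification")
    if age < 18 or weight <= 0:
        raise InvalidInputError(f"invalid age/weight ({age}, {weight})")

    if age < 50:
        age_band = AgeBand.UNDER50
    elif age < 70:
        age_band = AgeBand.FROM50TO69
    else:
        age_band = AgeBand.OVER70

    if weight < 60:
        weight_band = WeightBand.UNDER60
    elif weight < 70:
        weight_band = WeightBand.FROM60TO69
    elif weight <= 90:
        weight_band = WeightBand.FROM70TO90
    else:
        weight_band = WeightBand.OVER90

    return Stratum(age_band, weight_band)


_ARMS = (Arm.BW, Arm.LBW, Arm.CO)


def _validate_block_sizes(block_sizes: Sequence[int]) -> tuple[int, ...]:
    sizes = tuple(sorted(set(int(s) for s in block_sizes)))
    if not sizes:
        raise ConfigError("block_sizes must be non-empty")
    for s in sizes:
        if s <= 0 or s % len(_ARMS) != 0:
            raise ConfigError(f"block size {s} is not a positive multiple of 3")
    return sizes


def _seed_fingerprint(seed: int, block_sizes: tuple[int, ...]) -> str:
    payload = f"seed={seed};blocks={block_sizes}".encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def randomize(
    patients: Iterable[PatientProfile],
    seed: int,
    block_sizes: Sequence[int] = (3, 6),
) -> list[Allocation]:
    """Allocate an ordered patient stream 1:1:1 across the three arms.

    Identical ``(patients, seed, block_sizes)`` yield identical allocations.
    Each stratum draws from an independent substream of ``seed``, so the
    schedule of one stratum does not depend on arrivals in the others.
    """
    sizes = _validate_block_sizes(block_sizes)
    fingerprint = _seed_fingerprint(seed, sizes)
    rngs = {
        stratum: np.random.default_rng(np.random.SeedSequence([int(seed), idx]))
        for idx, stratum in enumerate(ALL_STRATA)
    }
    # per-stratum open block: [block_index, next_position, remaining arms]
    pending: dict[Stratum, list] = {}
    blocks_opened: dict[Stratum, int] = {s: 0 for s in ALL_STRATA}

    allocations: list[Allocation] = []
    for patient in patients:
        stratum = stratum_of(patient)
        if stratum not in pending or not pending[stratum][2]:
            rng = rngs[stratum]
            size = int(rng.choice(sizes))
            arms = [a for a in _ARMS for _ in range(size // len(_ARMS))]
            order = [arms[i] for i in rng.permutation(size)]
            pending[stratum] = [blocks_opened[stratum], 0, order]
            blocks_opened[stratum] += 1
        entry = pending[stratum]
        arm = entry[2].pop(0)
        allocations.append(
            Allocation(
                patient_id=patient.id,
                arm=arm,
                stratum=stratum,
                block_index=entry[0],
                position_in_block=entry[1],
                seed_fingerprint=fingerprint,
            )
        )
        entry[1] += 1
    return allocations
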