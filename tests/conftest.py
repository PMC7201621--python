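import logging

import numpy as np
import pytest

from cmtrial.cohort import CohortSpec, generate_cohort
from cmtrial.protocol import PatientProfile, Sex

# the plausibility warnings for extreme simulated flows are expected noise
logging.getLogger("cmtrial.protocol").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mean_patient() -> PatientProfile:
    """A patient at the cohort-mean covariates."""
    return PatientProfile(
        id="MEAN", sex=Sex.MALE, age=60, height=173.0, weight=83.3, heart_rate=65.5
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A reproducible 327-patient cohort at the default spec."""
    return generate_cohort(CohortSpec(n=327), seed=20170417)


@pytest.fixture(scope="session")
def big_cohort():
    """A 10,000-patient cohort for moment-recovery and calibration checks."""
    return generate_cohort(CohortSpec(n=10_000), seed=20170418)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_patient(rng: np.random.Generator, pid: str = "R") -> PatientProfile:
    return PatientProfile(
        id=pid,
        sex=Sex.FEMALE if rng.random() < 0.5 else Sex.MALE,
        age=int(rng.integers(18, 90)),
        height=float(rng.uniform(140, 200)),
        weight=float(rng.uniform(45, 140)),
        heart_rate=float(rng.uniform(45, 110)),
    )
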