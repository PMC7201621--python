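"""Typed tabular interchange: dataclass <-> DataFrame <-> CSV, plus schema
validation for every file the pipeline reads or writes.

All interchange is plain CSV with typed header schemas; round-tripping a
table through its writer and reader is lossless at float repr precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import SimulatedPatient
from .design import AgeBand, Allocation, WeightBand
from .errors import InvalidInputError
from .imaging import ROIMeasurementSet, SegmentMeasurement
from .protocol import (
    Arm,
    InjectionPrescription,
    PatientProfile,
    ScanProtocol,
    Sex,
)
from .quality import PatientQuality, WindowClass

__all__ = [
    "patients_to_frame",
    "frame_to_patients",
    "allocations_to_frame",
    "prescriptions_to_frame",
    "roi_to_frame",
    "frame_to_roi",
    "quality_to_frame",
    "read_table",
    "write_table",
    "validate_schema",
    "SCHEMAS",
]


def patients_to_frame(
    patients: Sequence[SimulatedPatient],
    scan_protocols: Optional[Sequence[ScanProtocol]] = None,
    tube_voltages: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    rows = []
    for i, p in enumerate(patients):
        rows.append(
            {
                "patient_id": p.profile.id,
                "sex": p.profile.sex.value,
                "age": p.profile.age,
                "height_cm": p.profile.height,
                "weight_kg": p.profile.weight,
                "heart_rate_bpm": p.profile.heart_rate,
                "true_co_l_min": p.true_co,
                "deviation_flag": p.deviation_flag,
                "scan_protocol": scan_protocols[i].value if scan_protocols else "",
                "tube_voltage": tube_voltages[i] if tube_voltages else np.nan,
            }
        )
    return pd.DataFrame(rows)


def frame_to_patients(frame: pd.DataFrame) -> list[SimulatedPatient]:
    patients = []
    for row in frame.itertuples(index=False):
        profile = PatientProfile(
            id=str(row.patient_id),
            sex=Sex(row.sex),
            age=int(row.age),
            height=float(row.height_cm),
            weight=float(row.weight_kg),
            heart_rate=float(row.heart_rate_bpm),
        )
        patients.append(
            SimulatedPatient(
                profile=profile,
                true_co=float(row.true_co_l_min),
                deviation_flag=bool(row.deviation_flag),
            )
        )
    return patients


def allocations_to_frame(allocations: Sequence[Allocation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [a.patient_id for a in allocations],
            "arm": [a.arm.value for a in allocations],
            "age_band": [a.stratum.age_band.value for a in allocations],
            "weight_band": [a.stratum.weight_band.value for a in allocations],
            "block_index": [a.block_index for a in allocations],
            "position_in_block": [a.position_in_block for a in allocations],
            "seed_fingerprint": [a.seed_fingerprint for a in allocations],
        }
    )


def prescriptions_to_frame(
    prescriptions: Sequence[InjectionPrescription],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in prescriptions],
            "arm": [p.arm.value for p in prescriptions],
            "flow_rate": [p.flow_rate for p in prescriptions],
            "test_bolus_volume": [p.test_bolus_volume for p in prescriptions],
            "main_bolus_volume": [p.main_bolus_volume for p in prescriptions],
            "test_duration": [p.test_duration for p in prescriptions],
            "main_duration": [p.main_duration for p in prescriptions],
            "idr": [p.idr for p in prescriptions],
            "til": [p.til for p in prescriptions],
            "requires_high_flow_needle": [
                p.requires_high_flow_needle for p in prescriptions
            ],
        }
    )


def roi_to_frame(measurement_sets: Sequence[ROIMeasurementSet]) -> pd.DataFrame:
    rows = []
    for mset in measurement_sets:
        for seg in mset.segments:
            rows.append(
                {
                    "patient_id": mset.patient_id,
                    "segment_label": seg.label,
                    "vessel_hu": seg.vessel_hu,
                    "vessel_sd": seg.vessel_sd,
                    "fat_hu": mset.fat_hu,
                    "fat_sd": mset.fat_sd,
                    "artifact_flag": mset.artifact_flag,
                    "artifact_severity": mset.artifact_severity,
                }
            )
    return pd.DataFrame(rows)


def frame_to_roi(frame: pd.DataFrame) -> list[ROIMeasurementSet]:
    msets = []
    for pid, group in frame.groupby("patient_id", sort=False):
        first = group.iloc[0]
        msets.append(
            ROIMeasurementSet(
                patient_id=str(pid),
                segments=tuple(
                    SegmentMeasurement(
                        label=int(r.segment_label),
                        vessel_hu=float(r.vessel_hu),
                        vessel_sd=float(r.vessel_sd),
                    )
                    for r in group.itertuples(index=False)
                ),
                fat_hu=float(first["fat_hu"]),
                fat_sd=float(first["fat_sd"]),
                artifact_flag=bool(first["artifact_flag"]),
                artifact_severity=str(first["artifact_severity"]),
            )
        )
    return msets


def quality_to_frame(qualities: Sequence[PatientQuality]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [q.patient_id for q in qualities],
            "overall_hu": [q.overall_hu for q in qualities],
            "noise": [q.noise for q in qualities],
            "cnr": [q.cnr for q in qualities],
            "snr": [q.snr for q in qualities],
            "window": [q.window.value for q in qualities],
            "in_window": [q.in_window for q in qualities],
            "diagnostic": [q.diagnostic for q in qualities],
            "likert": [q.likert for q in qualities],
        }
    )


# --- schema validation -----------------------------------------------------

_BOOLS = {"True", "False", "true", "false", "0", "1"}


@dataclass(frozen=True)
class _Column:
    name: str
    kind: str  # "str" | "int" | "float" | "bool"
    check: Optional[Callable[[object], bool]] = None
    message: str = ""


SCHEMAS: dict[str, dict] = {
    "patients": {
        "key": "patient_id",
        "columns": [
            _Column("patient_id", "str"),
            _Column("sex", "str", lambda v: v in {s.value for s in Sex}, "unknown sex"),
            _Column("age", "int", lambda v: v >= 18, "age below 18"),
            _Column("height_cm", "float", lambda v: 100 < v < 250, "height outside (100, 250)"),
            _Column("weight_kg", "float", lambda v: 30 < v < 250, "weight outside (30, 250)"),
            _Column("heart_rate_bpm", "float", lambda v: v > 0, "non-positive heart rate"),
            _Column("true_co_l_min", "float", lambda v: v > 0, "non-positive cardiac output"),
            _Column("deviation_flag", "bool"),
        ],
    },
    "allocations": {
        "key": "patient_id",
        "columns": [
            _Column("patient_id", "str"),
            _Column("arm", "str", lambda v: v in {a.value for a in Arm}, "unknown arm"),
            _Column("age_band", "str", lambda v: v in {b.value for b in AgeBand}, "unknown age band"),
            _Column("weight_band", "str", lambda v: v in {b.value for b in WeightBand}, "unknown weight band"),
            _Column("block_index", "int", lambda v: v >= 0, "negative block index"),
            _Column("position_in_block", "int", lambda v: v >= 0, "negative position"),
        ],
    },
    "prescriptions": {
        "key": "patient_id",
        "columns": [
            _Column("patient_id", "str"),
            _Column("arm", "str", lambda v: v in {a.value for a in Arm}, "unknown arm"),
            _Column("flow_rate", "float", lambda v: v > 0, "non-positive flow"),
            _Column("test_bolus_volume", "float", lambda v: v > 0, "non-positive volume"),
            _Column("main_bolus_volume", "float", lambda v: v > 0, "non-positive volume"),
            _Column("test_duration", "float", lambda v: v > 0, "non-positive duration"),
            _Column("main_duration", "float", lambda v: v > 0, "non-positive duration"),
            _Column("idr", "float", lambda v: v > 0, "non-positive IDR"),
            _Column("til", "float", lambda v: v > 0, "non-positive TIL"),
            _Column("requires_high_flow_needle", "bool"),
        ],
    },
    "roi": {
        "key": None,
        "columns": [
            _Column("patient_id", "str"),
            _Column("segment_label", "int", lambda v: 1 <= v <= 17, "segment outside 1-17"),
            _Column("vessel_hu", "float"),
            _Column("vessel_sd", "float", lambda v: v > 0, "non-positive vessel sd"),
            _Column("fat_hu", "float"),
            _Column("fat_sd", "float", lambda v: v > 0, "non-positive fat sd"),
            _Column("artifact_flag", "bool"),
        ],
    },
    "quality": {
        "key": "patient_id",
        "columns": [
            _Column("patient_id", "str"),
            _Column("overall_hu", "float"),
            _Column("noise", "float", lambda v: v > 0, "non-positive noise"),
            _Column("cnr", "float"),
            _Column("snr", "float"),
            _Column("window", "str", lambda v: v in {w.value for w in WindowClass}, "unknown window class"),
            _Column("in_window", "bool"),
            _Column("diagnostic", "bool"),
            _Column("likert", "int", lambda v: v in (1, 2, 3, 4), "Likert outside 1-4"),
        ],
    },
}


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def validate_schema(
    table: Union[pd.DataFrame, str, Path], schema_name: str
) -> list[dict]:
    """Check a table against a named schema; return per-row violations.

    Each violation is ``{"row": i, "field": name, "message": why}``; an
    empty list means the table is well formed. Row indices are 0-based data
    rows (header excluded).
    """
    if schema_name not in SCHEMAS:
        raise InvalidInputError(f"unknown schema {schema_name!r}")
    frame = read_table(table) if not isinstance(table, pd.DataFrame) else table
    schema = SCHEMAS[schema_name]
    violations: list[dict] = []

    for col in schema["columns"]:
        if col.name not in frame.columns:
            violations.append(
                {"row": -1, "field": col.name, "message": "missing column"}
            )
    if violations:
        return violations

    casts = {"int": int, "float": float, "str": str}
    for i, row in enumerate(frame.itertuples(index=False)):
        for col in schema["columns"]:
            raw = getattr(row, col.name)
            if col.kind == "bool":
                if not isinstance(raw, (bool, np.bool_)) and str(raw) not in _BOOLS:
                    violations.append(
                        {"row": i, "field": col.name, "message": "not a boolean"}
                    )
                continue
            try:
                value = casts[col.kind](raw)
            except (TypeError, ValueError):
                violations.append(
                    {"row": i, "field": col.name, "message": f"not a {col.kind}"}
                )
                continue
            if col.kind in ("int", "float") and not np.isfinite(value):
                violations.append(
                    {"row": i, "field": col.name, "message": "not finite"}
                )
                continue
            if col.check is not None and not col.check(value):
                violations.append(
                    {"row": i, "field": col.name, "message": col.message}
                )

    key = schema["key"]
    if key is not None:
        seen: dict = {}
        for i, value in enumerate(frame[key]):
            if value in seen:
                violations.append(
                    {
                        "row": i,
                        "field": key,
                        "message": f"duplicate id (first seen at row {seen[value]})",
                    }
                )
            else:
                seen[value] = i
    return violations
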