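"""End-to-end reproducible pipeline: cohort -> randomize -> prescribe ->
simulate imaging -> quality -> report.

A serialized :class:`RunConfig` plus its seed fully determines every output
byte. The root seed fans out into named substreams (one per stage) via
``numpy.random.SeedSequence``, so any stage can be re-run independently and
still see the same randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import tables
from .cohort import (
    CohortSpec,
    SimulatedPatient,
    assign_scan_protocol,
    assign_tube_voltage,
    kv_cutpoints,
    generate_cohort,
)
from .design import randomize
from .errors import ConfigError
from .imaging import (
    ResponseModel,
    calibrate_response,
    default_response_model,
    simulate_measurements,
)
from .protocol import Arm, ContrastAgent, ScanContext, derive_body, prescribe
from .quality import patient_quality, per_segment_summaries
from .reference import ATTENUATION_SUMMARY
from .stats import TrialReport, build_report
from .tables import write_table

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "PipelineResult"]

# Stage names in fan-out order; the index keys the substream.
_STAGES = ("cohort", "randomize", "calibration", "imaging")


def stage_seed(root_seed: int, stage: str) -> np.random.SeedSequence:
    """Named substream of the root seed for one pipeline stage."""
    try:
        idx = _STAGES.index(stage)
    except ValueError as exc:
        raise ConfigError(f"unknown stage {stage!r}") from exc
    return np.random.SeedSequence([int(root_seed), idx])


@dataclass(frozen=True)
class RunConfig:
    """Everything that determines one pipeline run."""

    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    model: ResponseModel = field(default_factory=default_response_model)
    block_sizes: tuple[int, ...] = (3, 6)
    bsa_method: str = "dubois"
    population: str = "itt"
    calibration_targets: dict = field(
        default_factory=lambda: {
            arm.value: ATTENUATION_SUMMARY[arm] for arm in Arm
        }
    )
    calibration_pilot_n: int = 2000
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["model"]["kv_gain"] = {int(k): v for k, v in self.model.kv_gain.items()}
        return out

    def config_hash(self) -> str:
        # out_dir is where artefacts land, not part of the run's identity
        payload = self.to_dict()
        payload.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "cohort" in kwargs:
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        if "model" in kwargs:
            model = dict(kwargs["model"])
            if "kv_gain" in model:
                model["kv_gain"] = {int(k): float(v) for k, v in model["kv_gain"].items()}
            kwargs["model"] = ResponseModel(**model)
        if "block_sizes" in kwargs:
            kwargs["block_sizes"] = tuple(kwargs["block_sizes"])
        if "calibration_targets" in kwargs:
            kwargs["calibration_targets"] = {
                str(k): tuple(v) for k, v in kwargs["calibration_targets"].items()
            }
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """In-memory handles to every artefact of one run."""

    config: RunConfig
    patients: pd.DataFrame
    allocations: pd.DataFrame
    prescriptions: pd.DataFrame
    roi: pd.DataFrame
    quality: pd.DataFrame
    segment_counts: pd.DataFrame
    report: TrialReport
    manifest: dict


def _scan_contexts(cohort: Sequence[SimulatedPatient], spec: CohortSpec):
    cutpoints = kv_cutpoints(spec)
    protocols, voltages = [], []
    for patient in cohort:
        protocols.append(assign_scan_protocol(patient.profile.heart_rate))
        voltages.append(assign_tube_voltage(patient.profile, cutpoints=cutpoints))
    return protocols, voltages


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage; write tables and a manifest if ``out_dir`` is set."""
    # 1. cohort + scan logistics
    cohort_seed = int(stage_seed(config.seed, "cohort").generate_state(1)[0] % (2**31))
    cohort = generate_cohort(config.cohort, seed=cohort_seed)
    protocols, voltages = _scan_contexts(cohort, config.cohort)
    contexts = [
        ScanContext(scan_protocol=p, tube_voltage=v)
        for p, v in zip(protocols, voltages)
    ]
    patients_df = tables.patients_to_frame(cohort, protocols, voltages)

    # 2. randomization
    rand_seed = int(
        np.random.SeedSequence([config.seed, _STAGES.index("randomize")]).generate_state(1)[0]
    )
    allocations = randomize(
        [p.profile for p in cohort], seed=rand_seed, block_sizes=config.block_sizes
    )
    alloc_df = tables.allocations_to_frame(allocations)
    arm_of = {a.patient_id: a.arm for a in allocations}

    # 3. prescriptions
    prescriptions = []
    for patient, context in zip(cohort, contexts):
        derived = derive_body(patient.profile, bsa_method=config.bsa_method)
        prescriptions.append(
            prescribe(
                patient.profile,
                context,
                arm_of[patient.profile.id],
                agent=ContrastAgent(),
                bsa_method=config.bsa_method,
                derived=derived,
            )
        )
    rx_df = tables.prescriptions_to_frame(prescriptions)

    # 4. imaging: per-arm calibration on a pilot cohort, then simulation
    calib_ss = stage_seed(config.seed, "calibration")
    pilot_spec = dataclasses.replace(
        config.cohort, n=config.calibration_pilot_n, seed=None
    )
    pilot_seed = int(calib_ss.generate_state(1)[0] % (2**31))
    pilot = generate_cohort(pilot_spec, seed=pilot_seed)
    pilot_protocols, pilot_voltages = _scan_contexts(pilot, config.cohort)
    pilot_contexts = [
        ScanContext(p, v) for p, v in zip(pilot_protocols, pilot_voltages)
    ]
    calibrated = {}
    for arm_label, (target_mean, target_sd) in config.calibration_targets.items():
        arm = Arm(arm_label)
        pilot_rx = [
            prescribe(p.profile, c, arm, bsa_method=config.bsa_method)
            for p, c in zip(pilot, pilot_contexts)
        ]
        calibrated[arm] = calibrate_response(
            config.model,
            pilot,
            pilot_rx,
            pilot_contexts,
            target_mean=target_mean,
            target_sd=target_sd,
            seed=pilot_seed,
        )

    imaging_ss = stage_seed(config.seed, "imaging")
    child_seeds = imaging_ss.spawn(len(cohort))
    measurement_sets = []
    for patient, rx, context, child in zip(cohort, prescriptions, contexts, child_seeds):
        model = calibrated[arm_of[patient.profile.id]]
        measurement_sets.append(
            simulate_measurements(
                patient, rx, context, model, rng=np.random.default_rng(child)
            )
        )
    roi_df = tables.roi_to_frame(measurement_sets)

    # 5. quality analysis
    qualities = [patient_quality(m) for m in measurement_sets]
    quality_df = tables.quality_to_frame(qualities)
    seg_rows = []
    for arm in sorted({a.value for a in arm_of.values()}):
        arm_sets = [
            m for m in measurement_sets if arm_of[m.patient_id].value == arm
        ]
        summary = per_segment_summaries(arm_sets)
        seg_rows.append({"arm": arm, **{k: summary[k] for k in (
            "n_segments", "n_in_window", "n_diagnostic", "n_good_excellent")}})
    segment_counts = pd.DataFrame(seg_rows)

    # 6. report
    deviation_flags = {p.profile.id: p.deviation_flag for p in cohort}
    report = build_report(
        quality_df,
        rx_df,
        alloc_df,
        population=config.population,
        deviation_flags=deviation_flags,
        segment_counts=segment_counts,
    )

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "row_counts": {
            "patients": int(len(patients_df)),
            "allocations": int(len(alloc_df)),
            "prescriptions": int(len(rx_df)),
            "roi_rows": int(len(roi_df)),
            "quality": int(len(quality_df)),
            "report_n": int(sum(report.n_per_arm.values())),
        },
        "population": config.population,
        "calibrated_patient_noise_sd": {
            arm.value: calibrated[arm].patient_noise_sd for arm in calibrated
        },
    }

    result = PipelineResult(
        config=config,
        patients=patients_df,
        allocations=alloc_df,
        prescriptions=rx_df,
        roi=roi_df,
        quality=quality_df,
        segment_counts=segment_counts,
        report=report,
        manifest=manifest,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(patients_df, out / "patients.csv")
        write_table(alloc_df, out / "allocations.csv")
        write_table(rx_df, out / "prescriptions.csv")
        write_table(roi_df, out / "roi.csv")
        write_table(quality_df, out / "quality.csv")
        write_table(segment_counts, out / "segment_counts.csv")
        (out / f"report_{config.population}.json").write_text(
            report.to_json(indent=2)
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
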