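#!/usr/bin/env python
"""Compute every patient's personalized contrast-media prescription.

Each patient is dosed under their allocated arm (body weight, Hume lean
body weight, or Katori cardiac output), adapted to tube voltage and scan
time. Writes results/prescriptions.csv and prints the dosing summary in
the shape of the published injection-parameter table.
"""

from cmtrial import tables
from cmtrial.protocol import Arm, ScanContext, ScanProtocol, prescribe

patients_frame = tables.read_table("results/patients.csv")
patients = tables.frame_to_patients(patients_frame)
alloc = tables.read_table("results/allocations.csv")
arm_of = dict(zip(alloc["patient_id"], alloc["arm"]))

prescriptions = []
for patient, row in zip(patients, patients_frame.itertuples(index=False)):
    context = ScanContext(ScanProtocol(row.scan_protocol), int(row.tube_voltage))
    prescriptions.append(
        prescribe(patient.profile, context, Arm(arm_of[patient.profile.id]))
    )
frame = tables.prescriptions_to_frame(prescriptions)
tables.write_table(frame, "results/prescriptions.csv")

print(f"prescribed {len(prescriptions)} injections -> results/prescriptions.csv")
header = f"  {'variable':20s}" + "".join(f"{a.value:>16s}" for a in Arm)
print(header)
for var, label in [
    ("main_bolus_volume", "CM volume (mL)"),
    ("test_bolus_volume", "test bolus (mL)"),
    ("flow_rate", "flow rate (mL/s)"),
    ("idr", "IDR (gI/s)"),
    ("til", "TIL (gI)"),
]:
    cells = []
    for arm in Arm:
        v = frame.loc[frame["arm"] == arm.value, var].to_numpy()
        cells.append(f"{v.mean():7.1f}+/-{v.std(ddof=1):4.1f}")
    print(f"  {label:20s}" + "".join(f"{c:>16s}" for c in cells))
n_needle = int(frame["requires_high_flow_needle"].sum())
print(f"  high-flow needle required: {n_needle} patients (flow > 7 mL/s)")
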