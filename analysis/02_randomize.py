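#!/usr/bin/env python
"""Randomize the cohort 1:1:1 with stratified variable permuted blocks.

Reads results/patients.csv, allocates on age x weight strata with block
sizes {3, 6}, and writes results/allocations.csv. Prints arm totals and the
worst per-stratum imbalance (bounded by 4 by the block design).
"""

import collections

from cmtrial import tables
from cmtrial.design import randomize
from cmtrial.protocol import Arm

SEED = 327

patients = [p.profile for p in tables.frame_to_patients(
    tables.read_table("results/patients.csv"))]
allocations = randomize(patients, seed=SEED, block_sizes=[3, 6])
tables.write_table(tables.allocations_to_frame(allocations), "results/allocations.csv")

totals = collections.Counter(a.arm for a in allocations)
print(f"allocated {len(allocations)} patients -> results/allocations.csv")
print("  arm totals:", {a.value: totals[a] for a in Arm})
per_stratum = collections.defaultdict(collections.Counter)
for a in allocations:
    per_stratum[a.stratum][a.arm] += 1
worst = max(
    max(c[a] for a in Arm) - min(c[a] for a in Arm) for c in per_stratum.values()
)
print(f"  strata used: {len(per_stratum)} of 12; worst within-stratum imbalance: {worst}")
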