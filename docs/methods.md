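# Methods

## What the package computes

`cmtrial` implements a three-arm comparison of personalized contrast-media
(CM) injection protocols for coronary CT angiography (CCTA) as a fully
executable pipeline. The three personalization strategies prescribe the CM
flow rate from tube voltage (kV) and one body parameter each:

```
BW arm :  flow = 0.0007976 * kV * BW            (BW: body weight, kg)
LBW arm:  flow = 0.001101  * kV * LBW           (Hume lean body weight, kg)
CO arm :  flow = 0.008916  * kV * CO            (adapted Katori cardiac output, L/min)
```

with

```
LBW(male)   = 0.32810*W + 0.33929*L - 29.5336
LBW(female) = 0.29569*W + 0.41813*L - 43.2933       (W kg, L cm)
CO          = (4.874 - 0.023*age) * BSA              (age y, BSA m^2)
```

Injection times are fixed: 2 s for the test bolus and 8 s (high-pitch
"flash") or 10 s (adaptive sequence, helical) for the main bolus, so bolus
volumes are flow x time. With the 300 mgI/mL agent, the iodine delivery
rate is IDR = 0.3 x flow (gI/s) and the total iodine load TIL = 0.3 x main
volume (gI). Flows above 7 mL/s set a high-flow-needle flag (325 psi rated
catheter); flows outside 1-12 mL/s are logged as implausible but still
prescribed, because in practice such orders are adjusted at the table, not
rejected.

### Body-surface-area estimator

No specific BSA equation is mandated by the dosing scheme, so the
estimator is a selectable strategy. Du Bois-Du Bois
(0.007184 W^0.425 H^0.725) is the default because at the cohort-mean
covariates (83.3 kg, 173 cm) it gives 1.97 m^2, matching the reported
baseline BSA of 2.0 +/- 0.2 m^2; Mosteller (sqrt(WH/3600)) is available by
flag for auditability.

## Trial machinery

**Randomization.** 1:1:1 allocation with variable random permuted blocks,
stratified on age (<50, 50-69, >=70 y) x weight (<60, 60-69, 70-90,
>90 kg) = 12 strata. The printed bands leave 69-70 unassigned; the
implementation closes them half-open ([50,70) years, [60,70) kg) with
70 kg and 90 kg in the 70-90 band, so stratification is a total function.
Block sizes default to {3, 6} (the sizes used in practice are unreported);
each stratum consumes an independent substream of the seed, so allocations
are reproducible and independent of arrivals in other strata. Per-stratum
imbalance at any point of the stream is bounded by max-block-size x 2/3 = 4.

**Synthetic cohort.** Virtual patients are drawn from truncated-normal
marginals parameterized by the published baseline table (n=327; weight
83.3 +/- 15.9 kg; height 173 +/- 10 cm; age 60 +/- 10.6 y; heart rate
65.5 +/- 13.1 bpm; 51.4% women), with a configurable height-weight
correlation (default 0.4) and a +/-6.5 cm sex offset on height. Offsets
and correlations are folded into the marginal moments (within-sex
variances are shrunk accordingly), so pooled means/sds still match the
configured values; truncation sits several sds out and shifts moments
negligibly (the weight sd of the truncated population is 15.86 rather
than 15.9).

Heart rate is right-skewed in this population (beta blockade drives most
patients below 70 bpm while atrial-fibrillation referrals stay high), and
a symmetric normal cannot reproduce both the published moments and the
published scan-protocol shares. Heart rate is therefore a mixture: a
lognormal majority plus a 5% tachycardic normal component at 95 +/- 10
bpm, with the majority's parameters solved so the pooled mean/sd equal the
configured values exactly. At the defaults this yields protocol shares of
~69% flash (<=70 bpm), ~26% adaptive sequence (70-90 bpm) and ~5% helical
(>90 bpm), matching the reported usage. The boundary at exactly 70 bpm
goes to flash (the "<=" is explicit in the protocol table).

Each patient carries a latent "true" cardiac output: the Katori estimate
times a mean-one lognormal multiplier (sigma = 0.10 by default; 0 makes
the formula exact). This makes formula-based personalization an imperfect
proxy for physiology in a controlled way - in particular the CO arm doses
on the estimate while the simulator dilutes by the latent value. A
deviation flag (p = 41/327 ~ 0.125) models non-adherence to the assigned
injection protocol and drives the per-protocol population.

**Tube-voltage surrogate.** The scanner's automated tube-voltage selection
is emulated by a deterministic, monotone BMI-quantile rule: BMI cutpoints
are the quantiles of a large fixed-seed sample from the cohort spec at the
published kV usage shares (40% 70 kV, 39% 80 kV, 10% 90 kV, 5% 100 kV,
6% 120 kV; 110 kV saw zero use and is omitted). Heavier patients never
receive a lower kV than lighter ones. This is plumbing, not physics: only
the resulting kV distribution is knowable from the published record.

## Attenuation simulator

No quantitative attenuation response accompanies the published record, so
per-segment measurements come from an explicit surrogate model:

```
patient mean HU  = gain(kV) * IDR / CO_true + patient_noise
segment HU       = patient mean + segment_noise
```

This is the simplest response carrying the qualitative physiology that
motivates the trial: attenuation rises with iodine delivery rate, falls
with cardiac output (dilution), and rises toward low kV (iodine K-edge).
The default gain follows `g0 * (100/kV)^1.3`, the approximate power law of
iodine contrast versus tube voltage. The exponent matters: prescribed flow
is itself proportional to kV, so a pure 1/kV gain would cancel voltage
exactly, while the 1.3 power leaves the intended weak net kV dependence
and keeps the between-patient signal spread inside the published sd. The
model is pluggable so a pharmacokinetic alternative can be substituted.

**Calibration.** `calibrate_response` rescales the gain map
multiplicatively (the response is linear in gain) and solves the
between-patient noise from the variance budget left after the
dosing-driven signal spread and the segment-averaging term, then verifies
by simulation (default tolerance +/-5 HU on mean and sd; bounded
iterations; deterministic given a seed). If the irreducible signal spread
already exceeds the target sd the noise floors at 0 and, when the result
is still outside tolerance, calibration fails with diagnostics rather
than silently degrading. At the default conditions the BW arm calibrated
to 423 +/- 60 HU lands near 423 +/- 62.5.

**Free parameters with documented defaults.** Epicardial fat ROI:
-90 +/- 10 HU with its own sd 35 +/- 5 HU (typical adipose values; chosen
so CNR = (vessel - fat)/fat_sd lands near the reported 14). Intravascular
noise: patient-level mean 39 HU with between-patient sd 8 HU and a 4 HU
within-patient residual, matching the reported per-patient noise 39 +/- 8
under the mean-of-segments convention. Assessable segments per patient:
12-16 with mean 14.3 (1,599 segments / 112 patients in the largest arm).
Artifacts: 3% of scans, split minimal/minor/major 50/35/15.

## Outcomes and statistics

Per patient: overall attenuation = mean vessel HU over all present
segments; noise = mean of per-segment vessel sds (whether the original
reading used this or a single ROI is unknowable; the convention is fixed
and documented); CNR = (vessel - fat)/fat_sd; SNR = vessel/noise. The
optimal window is 325-500 HU with both bounds inclusive (>=325 is
explicitly diagnostic; ">500" is the stated overshoot condition, so 500
itself is optimal). The 4-point Likert reading is replaced by a frozen
rule: 4 = no artifacts and >=325 HU; 3 = minimal artifacts and >=325 HU;
2 = minor artifacts or sub-325 attenuation; 1 = major artifacts or
sub-325 attenuation with artifacts. Per-segment proportions pool segments
across patients and treat them as independent observations, replicating
the original analysis convention; the within-patient clustering caveat
applies to both.

Group comparisons follow the original software defaults: two-sided
Student's t with pooled variance (Welch by flag), Pearson chi-square
without continuity correction, alpha = 0.05, no multiple-testing
adjustment. The continuity-corrected statistic on the reconstructed
good-excellent table gives p ~ 0.054 against the published 0.031, so the
uncorrected form is demonstrably the one used. Degenerate inputs follow
explicit conventions: identical constant samples give t=0, p=1; zero
marginals raise. `reconstruct_counts` inverts printed percentages to
integer numerators (half-away-from-zero rounding, the printed tables'
convention) and raises on ambiguity. Both intention-to-treat and
per-protocol (deviation-flagged patients excluded) populations are
reported.

## What passing tests do and do not show

The synthetic cohort reproduces the published marginal summaries, not the
real joint distribution (sex-conditional height/weight laws were never
printed), and the attenuation simulator is calibrated to the published
group moments, not estimated from images. Consequently the pipeline
demonstrates that the dosing arithmetic, randomization design, outcome
definitions and statistics behave as specified, and that the published
tables are internally consistent - it cannot and does not re-derive the
trial's measured attenuation outcomes, which depend on unreleased images.
The one-decimal dosing consistency checks, the reconstructed-count
chi-square p-values (0.031 / 0.947 / 0.102), and the formula spot checks
(BSA 1.97 m^2, CO 6.90 L/min, LBW 55.1 kg at cohort means) are exact
reproductions; everything attenuation-shaped is a calibration-closure or
monotonicity property instead.

## Numerical choices and problem sizes

Internal arithmetic is unrounded; printed-table comparisons round half
away from zero to the table's decimals. Simulation studies in the test
suite and acceptance script use 10,000-patient cohorts for moment and
calibration checks, 327 for trial-sized runs, 2,000-patient pilots for
per-arm calibration inside the pipeline, 1,000 seeded replicates for
randomization balance, and the full enumeration of 2x2 tables with
margins <= 30 (162,315 tables) for the chi-square oracle sweep. All
randomness flows from a single root seed fanned out per stage through
named `SeedSequence` substreams, so identical configurations reproduce
byte-identical outputs.

## Known limitations

The response model is a one-compartment steady-state caricature: no bolus
geometry, no recirculation, no beam hardening, no per-vessel differences.
Injector peak pressure is observed hardware telemetry in the original
record and is not modelled. Printed test-bolus volumes slightly exceed
2 s x mean flow (e.g. 11.2 mL vs 10.2 mL in the BW arm); the published
protocol states the 2 s rule and offers no explanation for the surplus
(per-patient rounding-up or a minimum-volume floor are plausible), so the
engine implements the stated rule and leaves the discrepancy documented
rather than guessing a floor. Simulated dosing summaries therefore sit
slightly above the printed ones (which also reflect 41 protocol
deviations); the printed-table harness works from the printed means
directly and is unaffected.
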