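# Methods

This note records the models, conventions, parameter defaults, and design
choices behind `snakescomp`, and what the simulator's results do and do
not say about real observers.

## Display geometry and visual angles

The default geometry is a 1920×1080 panel viewed from 500 mm. The pixel
pitch is set to 0.27675 mm/px (a 24-inch 16:9 panel with 531.4 mm visible
width); with it, the full-angle span convention

    span(px) = 2·atan(px · pitch / 2 / distance)

converts 1500 px to 45.1° and 900 px to 28.0° after rounding. Disk
eccentricity uses the same convention centered on the line of sight:
`ecc(d) = atan(d·pitch/distance)`, i.e. half the span of twice the offset.
Note the two conventions disagree slightly for large extents (atan is
concave); the span convention is authoritative for extents, the half-span
form for eccentricities. A 150-px disk subtends 4.75° under this pitch;
no single pitch reproduces both the printed span conversions and a 4.73°
disk, so the span calibration was preferred.

Screen coordinates are raster-style (origin top-left, y down, 0-based),
which makes `atan2(dy, dx)` clockwise-positive as seen by the viewer;
disk orientations are therefore stored CW-positive.

## Stimulus rendering

Rendering is an analytic nearest-segment lookup per pixel in polar
coordinates around each disk center — no anti-aliasing — so rotational
invariants are bit-exact: the orientation is reduced modulo the pattern
period (4 segments × 9° = 36°) before lookup, making `render(θ)` and
`render(θ+36°)` identical rasters. The four-level cycle for clockwise
illusory motion is black → dark gray → white → light gray along the
direction of perceived motion; direction −1 mirrors the arrangement, and
the mirrored render equals the horizontal flip of the clockwise one
(180° is a whole number of color cycles). Rendering quality is adequate
for simulation and export, not for luminance-calibrated presentation.

## Event detection

A saccade is declared whenever the gaze displacement between sample *n*
and sample *n−2* (converted per-axis to degrees and combined
Euclidean-wise), divided by the elapsed ~22.2 ms, reaches 10.5 deg/s.
The two-frame rule trades accuracy for loop latency; per-sample
differentiation at 90 Hz is noisier, and longer averaging would make
closed-loop compensation sluggish. Consequences adopted deliberately:

* one physical saccade can emit several events (each supra-threshold
  window); downstream state treats events as clock resets, so this is
  semantically identical to detecting the saccade once;
* each contiguous run of invalid samples emits exactly one blink event at
  its onset, even a run shorter than the evaluation stride (conservative
  triggering);
* an evaluation straddling invalid samples counts only as the blink, not
  additionally as a saccade.

## Synthetic gaze

The generator is a statistical emulation of a 90 Hz consumer tracker, not
an ocular-motor model: gamma-distributed fixation durations (shape 4),
uniform saccade amplitudes with uniformly random direction, minimum-jerk
saccade trajectories with duration 21 + 2.2·amplitude ms (a standard
main-sequence approximation), white Gaussian fixational jitter
(0.05° SD default), and Poisson blink gaps. It returns its exact injected
event list, so detector tests never re-infer ground truth. It has no
drift, tremor, microsaccades, pursuit, or tracker-specific noise spectra;
detector performance measured on it bounds only gross misbehavior, not
real-tracker accuracy.

## Compensation policies

All policy velocities are expressed in each disk's illusory-motion frame
(negative = against perceived motion), so one signed constant covers CW
and CCW arrangements; the frame is mapped to screen rotation by the
disk's pattern direction. The temporal profile `f(t)` is a sum of
half-sine components clamped to zero beyond their individual timescales
plus a constant; coincident timescales sum independently. Before the
first detected event the elapsed time is treated as infinite: clamped
components contribute nothing and only constant terms act. A new event
during an active window restarts the window. During blinks the last
valid eye position is held for eccentricity. Integration is explicit per
tick at gaze cadence using actual sample spacing. The bundled policy
file carries the reference constants (detection 10.5 deg/s, peripheral
threshold 8.0°, window 300 ms, c_A −0.71, c_B −0.35, c_C −0.39,
c_U −0.14).

## Simulated observers

**Direction-judgment observer.** Deliberately phenomenological: the
probability of reporting rotation in the illusory direction under
compensation amplitude *A* at timescale Δt is Φ((A − PSE(Δt))/σ). True
PSEs per timescale are free parameters; σ defaults to 1.0 deg/s (the
order of between-subject spread), and 0.5 deg/s is used in
parameter-recovery runs. Because real psychometric slopes for this task
are unknown, recovery results validate the staircase machinery, not any
claim about human thresholds.

**Preference observer.** Its internal illusion is additive in the
illusory frame: a sustained spatial term (gain × eccentricity), a
transient term following a clamped-sinusoid profile of time since the
last event, and a baseline. Perceived motion of a side is the mean over
its disks of ∫|illusion + compensation| dt — "moved more" is unsigned,
so compensation nulls the percept — plus one asymmetry: physical
rotation *exceeding* the concurrent illusion is unmasked and veridically
visible, and contributes an extra `veridical_salience ×
max(|v| − illusion, 0)` term. With salience 0 (the default) real and
illusory motion are fully interchangeable and the exact-nulling
constructions used in tests hold to machine precision.

## Adaptive procedures

**PEST.** The classic Taylor–Creelman heuristics around a Wald
sequential test at target probability 0.5 (a left/right task tracks the
PSE): deviation limit W = 1 trial; on a decision the level moves toward
the PSE; the step halves at reversals, repeats on the second
same-direction step, and doubles from the third onward unless the step
preceding the most recent reversal was itself a doubling. Trials per
level are capped at 20 (deciding by the side of the expectation, ties
continuing the current run) to guarantee termination. A run ends once
the step has shrunk to the stop criterion — 2.0 → 0.0625 deg/s is five
halvings. The interleaved pair starts from +10 and −10 deg/s, picks the
next staircase uniformly at random, and reports the mean of the two
final levels; the combination rule and the end-at-stop-step convention
are package choices where the procedure's description admits variants.

**Adjustment.** The human knob-turner is replaced by seeded greedy
descent of the policy constant on the 0.025 grid, minimizing the
observer's own perceived motion of the stimulus under a fixed
calibration gaze stream; ties break toward smaller |c|, two repeats with
independent streams are averaged (hence results on a 0.0125 grid), and a
walk reaching the grid bounds raises instead of silently clamping.

## Scoring

Per-subject policy score = mean of the probit-transformed corrected
selection ratios against the four opponents (the least-squares Thurstone
Case V solution for a complete balanced design; whether to average
probits or pool the 48 trials is not determined by the protocol
description, and the mean-of-probits reading is adopted). The (0, 12)
cell is corrected to (0.5, 11.5) and, symmetrically, (12, 0) to
(11.5, 0.5). Pairwise tests are two-sample z with unpooled variances,
two-sided, multiplied by the 10 pairs and capped at 1. Quartiles use
linear interpolation. The Grubbs test is two-sided at α = 0.05, replaces
at most one value per call with the mean of the others, and reports an
approximate p from the t-distribution mapping.

## End-to-end experiment simulations

Sessions are reproducible from seed alone; all timestamps are simulated.
The preference study (policy comparison) uses seven virtual subjects
with jittered gains (spatial 0.05 ± 0.008 deg/s per deg, transient 0.30
± 0.05 × the reference temporal profile, baseline 0.02 ± 0.005 deg/s,
choice noise 0.15 deg, veridical salience 4).

A deliberate and load-bearing design choice: **calibration and
evaluation use different gaze statistics.** During adjustment the
virtual subject actively provokes the illusion (4.5 saccades/s, no
blinks), as a person hunting for residual motion does; during the ten-
second paired-comparison trials they view naturally (0.4 saccades/s,
12 blinks/min). Under identical statistics and a shared objective, a
calibrated constant rotation can never be worse than no compensation
(greedy descent only accepts improvements of the very functional being
judged), so the empirically motivated outcome that gaze-blind uniform
rotation performs *worse* than a still image requires exactly this kind
of asymmetry: the uniform policy soaks up the event-rich calibration
average, then keeps rotating — visibly, by the salience term — through
the quiet stretches of natural viewing. Gaze-contingent policies track
the state and are insensitive to the rate change. The simulated ordering
(medians A, B > O > U) is therefore a consistency demonstration of the
closed loop under observers built to favor gaze-contingent nulling, not
an independent prediction about human subjects.

Trial counts follow the protocols (10 tasks per condition after 10
training tasks in the preference-rate study; 12 trials per pair across
the 10 policy pairs; two adjustment repeats per policy), trial duration
defaults to 10 s, and side assignment is randomized per trial.
Counterbalancing splits subjects into illusion-first and control-first
block orders in the staircase study.

## Numerical choices and degenerate inputs

* `f(t)` accepts t = ∞ (constant term only) and rejects negative t.
* Pulse windows accept Δt = ∞ as constant rotation at the amplitude.
* Exact probability ties in forced choices are broken by a fair seeded
  coin; exact ratio 0/1 in the probit raises, directing callers to the
  zero-cell correction.
* Step sizes in PEST are dyadic by construction (2.0/2^k), so the stop
  comparison is exact in floating point.
* The renderer rejects overlapping disks and disks outside the raster.

## Known limitations

* No mechanistic model of the illusion (retinal adaptation, motion
  energy); all observer behavior is phenomenological, so passing tests
  validate the machinery and internal consistency, not perception.
* The 20-ms hardware loop latency of a physical implementation is not
  modeled (events act at sample cadence).
* Image-translation compensation is out of scope (rotation only).
* Supplementary per-subject data tables can be loaded through the
  best-effort workbook reader, but group-level reproduction from them is
  not part of the automated checks.
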