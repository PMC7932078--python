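# snakescomp

A desk-scale simulator for **gaze-contingent compensation of the rotating
snakes illusion (RSI)** — the motion illusion in which a static arrangement
of repeated black / dark-gray / white / light-gray wedges appears to rotate,
most strongly in peripheral vision and right after saccades or blinks.

The idea under study: if an eye tracker tells the display *when* a large eye
movement happened and *where* the observer is looking, the display can
physically rotate each illusory disk *against* its perceived motion and null
the percept. `snakescomp` models that closed loop end to end, without
hardware or human subjects, for perception-engineering researchers who want
to prototype, stress-test, or regression-test compensation policies:

* **stimulus** — RSI disk layouts (two 2×3 sets, or a 4×3 grid of 150-px
  disks), analytic grayscale rendering, pixel ⇄ visual-angle conversion for
  a 1920×1080 display viewed at 50 cm;
* **gaze** — 90 Hz tracker streams, CSV logs, and large-eye-movement
  detection: a saccade is a two-frame gaze velocity ≥ 10.5 deg/s, a blink a
  run of invalid samples;
* **synthetic_gaze** — seeded fixation/saccade/blink generators with exact
  ground truth (gamma fixations, minimum-jerk saccades with a
  main-sequence duration rule, Poisson blinks);
* **compensation** — the policies being compared, each rotating disks in
  their illusory-motion frame;
* **observer** — simulated psychophysical observers closing the loop;
* **psychophysics** — PEST adaptive staircases and adjustment-method
  calibration;
* **scoring** — selection rates, Thurstone paired-comparison probit scores
  with zero-cell correction, Bonferroni-corrected pairwise z tests, Grubbs
  outlier replacement;
* **session / cli** — full simulated experiments, reproducible from a seed.

## The model

After each detected saccade or blink the elapsed-time clock resets to
`t = 0`, and the transient strength of the illusion follows a sum of
clamped half-sine components (deg/s):

```
f(t[ms]) = 2.56 sin(πt/100) + 1.66 sin(πt/150) + 1.80 sin(πt/250)
         + 0.830 sin(πt/500) + 0.554 sin(πt/1000) + 0.277
```

where each component is identically zero for `t > Δt_i`, so `f` decays to
the constant 0.277 deg/s after one second.  Five compensation policies are
compared, each with a per-observer proportionality constant `c` calibrated
by the adjustment method (`θ` = disk eccentricity in deg):

| policy | rule | gaze information used |
|---|---|---|
| O | `v = 0` (still image) | — |
| A | `v(θ) = c_A · θ` | eye position |
| B | `v(t) = c_B · f(t)` | event timing |
| C | `v(t, θ) = c_C · θ · f(t)` | both |
| U | `v = c_U` | none |

Nulling amplitudes (points of subjective equality, PSE) are measured with
interleaved PEST staircases (Taylor–Creelman rules: initial levels
±10 deg/s, initial step 2.0, stop step 0.0625, Wald limit 1), and the
paired-comparison protocol scores each policy per subject as the mean
probit of its selection ratios against the four opponents, after replacing
extreme (0, 12) cells with (0.5, 11.5).

## Worked example

```python
import numpy as np
from snakescomp import (GazeSimConfig, generate, detect_events, DetectorConfig,
                        PsychometricObserver, run_pest_pair)
from snakescomp.session import SessionConfig, run_session

stream, truth = generate(GazeSimConfig(seed=0), duration_ms=10_000)
events = detect_events(stream, DetectorConfig())
print(f"samples: {len(stream)}, injected saccades: "
      f"{sum(e.kind == 'saccade' for e in truth)}, detected events: {len(events)}")

obs = PsychometricObserver(pse_by_timescale={100.0: -2.56}, response_sd=0.5, seed=1)
print(f"recovered PSE at 100 ms: {run_pest_pair(obs, 100.0, seed=1):+.3f} deg/s")

summary = run_session(SessionConfig(experiment="exp3", n_subjects=7, seed=1))["summary"]
print(summary[["ratio_larger", "q1", "median", "q3"]].round(3).to_string())
```

prints

```
samples: 900, injected saccades: 16, detected events: 31
recovered PSE at 100 ms: -2.562 deg/s
          ratio_larger     q1  median     q3
algorithm
O                 None -0.786  -0.765 -0.619
A                  7/7  0.325   0.971  1.212
B                  7/7  0.696   0.779  0.971
C                  7/7  0.367   0.761  0.943
U                  0/7 -1.688  -1.541 -1.437
```

The detector fires more often than saccades are injected because every
supra-threshold two-frame window during one physical saccade emits an event
(consumers treat events as clock resets, so this is harmless).  The PEST
pair recovers the observer's true nulling amplitude of −2.56 deg/s to
staircase resolution.  In the full paired-comparison simulation the
gaze-contingent policies (A, B, C) score above the still image O for every
virtual subject, while gaze-blind uniform rotation U — calibrated during
active scanning but evaluated under natural viewing — scores below it.

A CLI wraps the same functionality, e.g.:

```
snakescomp detect --gaze log.csv
snakescomp render --layout exp1_pair --policy B --out frames/
snakescomp run --config session.toml
```

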