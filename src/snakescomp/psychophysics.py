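"""Adaptive procedures: PEST staircases and adjustment-method calibration.

PEST (parameter estimation by sequential testing) tracks the point of
subjective equality of the direction-judgment task with the classic
Taylor & Creelman heuristics: a Wald sequential test decides at each
level whether responses deviate from the target probability, the level
then moves toward the PSE, the step halves on every reversal, repeats on
the second same-direction move, and doubles from the third onward unless
the step preceding the last reversal was itself a doubling.  A run ends
when the step falls below the stop criterion.  The reference settings
are initial levels of +/-10 deg/s, initial step 2.0 deg/s and stop step
0.0625 deg/s (five halvings), target probability 0.5 for a left/right
task, Wald limit W = 1.

Two staircases starting from the opposite extremes are randomly
interleaved so a (simulated) observer cannot predict the level sequence;
the PSE estimate is the mean of the two final levels.

The adjustment method replaces a human turning a knob: a seeded greedy
descent walks a policy's proportionality constant on a 0.025 grid,
minimizing the observer's own perceived net motion of the stimulus, and
averages two independent repeats (hence results on a 0.0125 grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compensation import CompensationPolicy, pulse_velocity, simulate_trial
from .gaze import DetectorConfig, GazeStream
from .observer import ILLUSORY_REPORT, PreferenceObserver, PsychometricObserver, judge_direction
from .stimulus import StimulusLayout

__all__ = [
    "PestConfig",
    "StaircaseState",
    "pest_update",
    "run_pest_pair",
    "run_adjustment",
]


@dataclass(frozen=True)
class PestConfig:
    initial_levels: tuple[float, float] = (10.0, -10.0)
    initial_step: float = 2.0
    stop_step: float = 0.0625
    target_p: float = 0.5
    wald_w: float = 1.0
    max_trials_per_level: int = 20
    max_trials: int = 1000

    def __post_init__(self) -> None:
        if self.initial_step <= 0 or self.stop_step >= self.initial_step:
            raise ValueError("need 0 < stop_step < initial_step")


@dataclass
class StaircaseState:
    """State of one PEST staircase tracking the PSE from one side."""

    level: float
    step: float
    config: PestConfig = field(default_factory=PestConfig)
    run_direction: int = 0  # +1 moving up, -1 moving down, 0 before first move
    same_direction_count: int = 0
    last_reversal_after_double: bool = False
    last_step_was_double: bool = False
    n_at_level: int = 0
    k_at_level: int = 0  # illusory-direction reports at the current level
    trial_history: list = field(default_factory=list)
    finished: bool = False

    @classmethod
    def fresh(cls, initial_level: float, config: PestConfig | None = None) -> "StaircaseState":
        config = config or PestConfig()
        return cls(level=initial_level, step=config.initial_step, config=config)

    def record(self, response_illusory: bool) -> None:
        self.trial_history.append((self.level, bool(response_illusory)))
        self.n_at_level += 1
        self.k_at_level += int(response_illusory)


def _wald_decision(state: StaircaseState) -> int:
    """+1 to raise the level, -1 to lower it, 0 to keep testing.

    The count of illusory-direction reports is compared against the
    expected count ``n*p`` with a deviation limit of W: too many such
    reports mean the compensation is too weak (level above the PSE), so
    the level must move down.  If the per-level trial cap is reached
    without a decision, the side of the expectation decides.
    """
    cfg = state.config
    n, k = state.n_at_level, state.k_at_level
    expected = n * cfg.target_p
    if k >= expected + cfg.wald_w:
        return -1
    if k <= expected - cfg.wald_w:
        return +1
    if n >= cfg.max_trials_per_level:
        if k > expected:
            return -1
        if k < expected:
            return +1
        return -1 if state.run_direction <= 0 else +1
    return 0


def pest_update(state: StaircaseState, response_illusory: bool) -> StaircaseState:
    """Feed one response into the staircase and apply the step rules.

    Mutates and returns ``state``.  Raises if the staircase is finished.
    """
    if state.finished:
        raise RuntimeError("cannot update a finished staircase")
    state.record(response_illusory)
    decision = _wald_decision(state)
    if decision == 0:
        return state

    cfg = state.config
    doubled = False
    if state.run_direction == 0:  # first move: keep the initial step
        state.same_direction_count = 1
    elif decision == state.run_direction:
        state.same_direction_count += 1
        if state.same_direction_count == 2:
            pass  # second same-direction step repeats its size
        elif state.same_direction_count == 3 and state.last_reversal_after_double:
            pass  # withhold the first doubling after such a reversal
        else:
            state.step *= 2.0
            doubled = True
    else:  # reversal: halve, remember if the pre-reversal step was doubled
        state.last_reversal_after_double = state.last_step_was_double
        state.step /= 2.0
        state.same_direction_count = 1
        # End condition: the run stops once the step has shrunk to the
        # stop criterion (2.0 -> 0.0625 is five halvings).
        if state.step <= cfg.stop_step:
            state.finished = True
    state.run_direction = decision
    state.last_step_was_double = doubled
    if not state.finished:
        state.level += decision * state.step
    state.n_at_level = 0
    state.k_at_level = 0
    return state


def run_pest_pair(
    obs: PsychometricObserver,
    dt_ms: float,
    config: PestConfig | None = None,
    seed: int = 0,
) -> float:
    """Interleaved pair of PEST staircases; returns the PSE estimate.

    Each trial presents a half-sine compensation pulse whose peak
    amplitude is the staircase level (constant rotation for dt = inf)
    and queries the observer's direction report.  The two staircases
    start from the opposite initial levels and are randomly interleaved;
    the estimate is the mean of their final levels.
    """
    config = config or PestConfig()
    rng = np.random.default_rng(seed)
    staircases = [StaircaseState.fresh(lv, config) for lv in config.initial_levels]
    trials = 0
    while any(not s.finished for s in staircases):
        open_idx = [i for i, s in enumerate(staircases) if not s.finished]
        s = staircases[int(rng.choice(open_idx))]
        # Present the pulse at the current level: its peak (mid-window,
        # or any time under constant rotation) is the judged amplitude.
        t_peak = 0.0 if math.isinf(dt_ms) else dt_ms / 2.0
        amplitude = pulse_velocity(s.level, dt_ms, t_peak)
        response = judge_direction(obs, amplitude, dt_ms) == ILLUSORY_REPORT
        pest_update(s, response)
        trials += 1
        if trials > config.max_trials:
            raise RuntimeError(
                f"PEST did not terminate within {config.max_trials} trials; "
                f"levels so far: {[s.level for s in staircases]}"
            )
    return float(np.mean([s.level for s in staircases]))


def run_adjustment(
    obs: PreferenceObserver,
    policy: CompensationPolicy,
    layout: StimulusLayout,
    make_stream,
    step: float = 0.025,
    repeats: int = 2,
    seed: int = 0,
    c_bounds: tuple[float, float] = (-4.0, 1.0),
    detector: DetectorConfig | None = None,
) -> float:
    """Calibrate a policy's constant by simulated adjustment.

    ``make_stream(seed) -> GazeStream`` supplies the gaze behaviour of
    the adjusting observer (each repeat gets an independent stream).
    Starting from c = 0, a greedy descent on the ``step`` grid minimizes
    the observer's perceived net motion of the stimulus under the policy;
    ties break toward smaller |c|.  The mean of the repeats is returned
    (a multiple of step/repeats).
    """
    if policy.kind not in ("A", "B", "C", "U"):
        raise ValueError("adjustment calibrates kinds A, B, C and U only")
    results = []
    for r in range(repeats):
        stream = make_stream(seed * 1000 + r)
        base = simulate_trial(layout, policy.with_constant(1.0), stream, detector)
        # Velocity is linear in c, so one unit-constant trace serves the
        # whole walk: v(c) = c * v(1).
        ill = obs.illusory_velocity(base.ecc_deg, base.t_since_event_ms)

        def perceived(c: float) -> float:
            return obs.percept_from(ill, c * base.v_comp, base.dt_ms)

        c = 0.0
        current = perceived(c)
        lo, hi = c_bounds
        while True:
            cand = []
            for nxt in (c - step, c + step):
                if lo <= nxt <= hi:
                    cand.append((perceived(nxt), abs(nxt), nxt))
            cand.sort()
            if cand and cand[0][0] < current - 1e-12:
                current, _, c = cand[0]
            else:
                break
        if c <= lo + step / 2 or c >= hi - step / 2:
            raise RuntimeError(f"adjustment walk hit the grid bound at c={c}")
        results.append(c)
    return float(np.mean(results))
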