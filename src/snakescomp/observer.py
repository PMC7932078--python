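"""Simulated psychophysical observers that close the experimental loop.

Two deliberately phenomenological models:

``PsychometricObserver`` answers the direction-judgment task ("did the
grid rotate left or right?") with a probit psychometric function around
a true nulling amplitude (point of subjective equality, PSE) per
compensation timescale.  It exists so adaptive staircases have a known
ground truth to recover; no mechanistic account of the illusion is
attempted, because the behaviour being emulated is characterised
entirely by its PSEs.

``PreferenceObserver`` answers the two-alternative preference task
("which side moved more?").  Its internal illusion is additive: a
sustained spatial component growing linearly with eccentricity, a
transient temporal component following a clamped-sinusoid profile of
time since the last large eye movement, and a baseline.  The perceived
net motion of a disk over a trial is the time integral of the absolute
net angular velocity (internal illusory velocity plus physical
compensation, both in the illusory-motion frame); "moved more" is
unsigned, so real and illusory rotation null each other in the percept.

One asymmetry between real and illusory motion is modeled: physical
rotation *exceeding* the concurrent illusion is not masked by it and is
perceived veridically, which makes it disproportionately conspicuous
(an observer watching a quiescent display immediately notices a disk
that actually turns).  The ``veridical_salience`` weight scales this
unmasked excess; at 0 (the default) real and illusory motion are fully
interchangeable and exact nulling constructions hold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compensation import TemporalFunction, TrialTrace, f_eval

__all__ = ["PsychometricObserver", "PreferenceObserver", "judge_direction", "choose_side"]

#: Convention: a report of "right" means rotation in the illusory (CW)
#: direction; "left" is the anti-illusory report.
ILLUSORY_REPORT = "right"
ANTI_ILLUSORY_REPORT = "left"


@dataclass
class PsychometricObserver:
    """Probit observer for the rotation-direction task.

    ``P(report illusory direction | amplitude A, timescale dt)`` is
    ``Phi((A - pse(dt)) / response_sd)``: with no compensation (A = 0
    above the negative PSE) the illusory direction is reported almost
    surely; at the nulling amplitude the two reports are equally likely.
    """

    pse_by_timescale: dict[float, float]
    response_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.response_sd < 0:
            raise ValueError("response_sd must be non-negative")
        self._rng = np.random.default_rng(self.seed)

    def p_illusory(self, amplitude: float, dt_ms: float) -> float:
        pse = self._pse(dt_ms)
        if self.response_sd == 0:
            return 1.0 if amplitude > pse else (0.5 if amplitude == pse else 0.0)
        # Standard normal CDF via erf keeps the hot path scipy-free.
        z = (amplitude - pse) / self.response_sd
        return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))

    def _pse(self, dt_ms: float) -> float:
        if dt_ms in self.pse_by_timescale:
            return self.pse_by_timescale[dt_ms]
        raise KeyError(f"no PSE configured for timescale {dt_ms!r}")


def judge_direction(obs: PsychometricObserver, amplitude: float, dt_ms: float) -> str:
    """Draw one direction report ("left"/"right"); seeded and reproducible."""
    p = obs.p_illusory(amplitude, dt_ms)
    return ILLUSORY_REPORT if obs._rng.random() < p else ANTI_ILLUSORY_REPORT


@dataclass
class PreferenceObserver:
    """Nulling observer for the two-alternative preference task.

    ``spatial_gain`` (deg/s per deg eccentricity) scales the sustained
    spatial illusion, ``temporal`` gives the transient component after
    large eye movements (its constant term should be 0; the sustained
    floor lives in ``baseline``), and ``choice_sd`` is decision noise on
    the perceived-motion difference (same units as the integral,
    deg-of-rotation).
    """

    spatial_gain: float = 0.05
    temporal: TemporalFunction = field(
        default_factory=lambda: TemporalFunction(components=((1.0, 500.0),))
    )
    baseline: float = 0.05
    choice_sd: float = 0.5
    veridical_salience: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.veridical_salience < 0:
            raise ValueError("veridical_salience must be non-negative")
        self._rng = np.random.default_rng(self.seed)

    def illusory_velocity(self, ecc_deg: np.ndarray, t_since_event_ms: np.ndarray) -> np.ndarray:
        """Internal illusory angular velocity (illusory frame, >= 0)."""
        ecc = np.asarray(ecc_deg, dtype=float)
        tse = np.asarray(t_since_event_ms, dtype=float)
        ft = np.full(tse.shape, self.temporal.constant)
        finite = np.isfinite(tse)
        if np.any(finite):
            ft[finite] = f_eval(self.temporal, tse[finite])
        return self.spatial_gain * ecc + ft[..., None] + self.baseline

    def percept_from(self, ill: np.ndarray, v_comp: np.ndarray, dt_ms: np.ndarray) -> float:
        """Perceived net motion given illusion/compensation velocity arrays.

        Mean over disks of the time integral of |ill + v| plus the
        salience-weighted unmasked physical excess max(|v| - ill, 0),
        in degrees of rotation.
        """
        w = np.asarray(dt_ms, dtype=float)[:, None] / 1000.0
        net = np.abs(ill + v_comp)
        if self.veridical_salience > 0:
            net = net + self.veridical_salience * np.maximum(np.abs(v_comp) - ill, 0.0)
        return float((net * w).sum(axis=0).mean())

    def perceived_motion(self, trace: TrialTrace) -> float:
        """Mean over disks of the integrated perceived net motion (deg)."""
        ill = self.illusory_velocity(trace.ecc_deg, trace.t_since_event_ms)
        return self.percept_from(ill, trace.v_comp, trace.dt_ms)


def choose_side(obs: PreferenceObserver, left_trace: TrialTrace, right_trace: TrialTrace) -> str:
    """Forced choice of the side perceived to move to a greater extent."""
    if len(left_trace.t_ms) != len(right_trace.t_ms):
        raise ValueError("traces must cover the same time span")
    diff = obs.perceived_motion(left_trace) - obs.perceived_motion(right_trace)
    if obs.choice_sd > 0:
        diff += obs._rng.normal(0.0, obs.choice_sd)
    if diff == 0.0:  # exact tie only in degenerate noiseless setups
        return "left" if obs._rng.random() < 0.5 else "right"
    return "left" if diff > 0 else "right"
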