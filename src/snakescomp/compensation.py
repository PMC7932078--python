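"""Compensation policies: event-triggered counter-rotation of RSI disks.

The illusory rotation of a rotating-snakes disk strengthens transiently
after large eye movements and grows with retinal eccentricity.  The
policies here physically rotate disks *against* their illusory motion to
null the percept:

* ``EXP1_THRESHOLD`` — constant angular velocity applied only to disks
  beyond a peripheral-vision threshold, for a fixed window after each
  detected saccade or blink.
* ``EXP2_PULSE`` — a half-sine velocity pulse ``I0 * sin(pi t / dt)``
  after each event, used to probe the temporal profile of the illusion.
* ``A`` — spatial: velocity proportional to disk eccentricity,
  continuously applied (no event gating).
* ``B`` — temporal: velocity proportional to the fitted temporal
  illusion profile ``f(t)`` of elapsed time since the last event.
* ``C`` — spatio-temporal: proportional to eccentricity times ``f(t)``.
* ``U`` — uniform: constant velocity, blind to gaze.
* ``O`` — no compensation (still image).

Velocities are signed in each disk's illusory-motion frame: a negative
value rotates against the perceived motion regardless of the CW/CCW
arrangement, which is why all fitted constants are negative.

The default temporal profile is the sum-of-clamped-sinusoids fit

    f(t[ms]) = 2.56 sin(pi t/100) + 1.66 sin(pi t/150)
             + 1.80 sin(pi t/250) + 0.830 sin(pi t/500)
             + 0.554 sin(pi t/1000) + 0.277,

where each component is identically zero for t beyond its timescale, so
f decays to the constant 0.277 deg/s after one second.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np

from .gaze import DetectorConfig, GazeEvent, GazeStream, detect_events
from .stimulus import DEFAULT_GEOMETRY, Disk, DisplayGeometry, StimulusLayout

__all__ = [
    "TemporalFunction",
    "CompensationPolicy",
    "CompensationState",
    "DEFAULT_TEMPORAL_FUNCTION",
    "f_eval",
    "eccentricity_deg",
    "policy_velocity",
    "threshold_velocity",
    "pulse_velocity",
    "advance",
    "simulate_trial",
    "TrialTrace",
    "load_policies",
    "default_policies",
]


@dataclass(frozen=True)
class TemporalFunction:
    """Sum of clamped half-sine components plus a constant (deg/s).

    Each ``(a_i, dt_i)`` component evaluates to ``a_i*sin(pi*t/dt_i)``
    for ``0 <= t <= dt_i`` and exactly 0 beyond, so the function decays
    to ``constant`` once every timescale has elapsed.  Components with
    equal timescales are summed independently.
    """

    components: tuple[tuple[float, float], ...]
    constant: float = 0.0

    def __post_init__(self) -> None:
        for a, dt in self.components:
            if dt <= 0:
                raise ValueError("component timescales must be positive")

    def __call__(self, t_ms):
        return f_eval(self, t_ms)

    def max_timescale_ms(self) -> float:
        return max((dt for _, dt in self.components), default=0.0)


DEFAULT_TEMPORAL_FUNCTION = TemporalFunction(
    components=((2.56, 100.0), (1.66, 150.0), (1.80, 250.0), (0.830, 500.0), (0.554, 1000.0)),
    constant=0.277,
)


def f_eval(tf: TemporalFunction, t_ms):
    """Evaluate the temporal profile at ``t_ms`` (scalar or array), deg/s.

    ``t = inf`` is allowed and yields the constant term alone.
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_ms must be non-negative")
    out = np.full(t.shape, tf.constant, dtype=float)
    for a, dt in tf.components:
        active = t <= dt
        out += np.where(active, a * np.sin(np.pi * np.where(active, t, 0.0) / dt), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CompensationPolicy:
    """A named compensation rule with its constants and thresholds.

    ``c`` is the proportionality constant for kinds A/B/C/U (deg/s per
    unit of the rule's argument); the threshold policy uses ``r_th_deg``,
    ``dt_ms`` and ``delta_theta_deg_per_s``; the pulse policy uses
    ``pulse_amplitude_deg_per_s`` and ``dt_ms`` (inf for constant
    rotation).
    """

    kind: str  # O | A | B | C | U | EXP1_THRESHOLD | EXP2_PULSE
    c: float = 0.0
    r_th_deg: float = 8.0
    dt_ms: float = 300.0
    delta_theta_deg_per_s: float = 0.0
    pulse_amplitude_deg_per_s: float = 0.0
    temporal: TemporalFunction = field(default_factory=lambda: DEFAULT_TEMPORAL_FUNCTION)

    KINDS = ("O", "A", "B", "C", "U", "EXP1_THRESHOLD", "EXP2_PULSE")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown policy kind: {self.kind!r}")

    def with_constant(self, c: float) -> "CompensationPolicy":
        return replace(self, c=c)


@dataclass
class CompensationState:
    """Elapsed time since the last detected large eye movement.

    Before any event the elapsed time is infinite: clamped sinusoid
    components contribute nothing and only constant terms are active.
    Reset to 0 on every saccade or blink.
    """

    t_since_event_ms: float = math.inf

    def reset(self) -> None:
        self.t_since_event_ms = 0.0

    def tick(self, dt_ms: float) -> None:
        self.t_since_event_ms += dt_ms


def eccentricity_deg(
    disk: Disk, eye_px: tuple[float, float], geometry: DisplayGeometry = DEFAULT_GEOMETRY
) -> float:
    """Visual angle between the gaze point and the disk center.

    Uses the span convention centered on the line of sight: the angle
    subtended by an on-screen offset ``d`` is ``atan(d*pitch/dist)``.
    """
    ex, ey = eye_px
    if not (math.isfinite(ex) and math.isfinite(ey)):
        raise ValueError("invalid eye sample; caller must hold the last valid position")
    d_px = math.hypot(disk.center_px[0] - ex, disk.center_px[1] - ey)
    return math.degrees(
        math.atan2(d_px * geometry.pixel_pitch_mm, geometry.viewing_distance_mm)
    )


def pulse_velocity(amplitude: float, dt_ms: float, t_ms: float) -> float:
    """Half-sine velocity pulse: ``A*sin(pi t/dt)`` for 0<=t<=dt, else 0.

    ``dt = inf`` means constant rotation at ``amplitude``.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive (use inf for constant rotation)")
    if math.isinf(dt_ms):
        return amplitude
    if t_ms < 0 or t_ms > dt_ms:
        return 0.0
    return amplitude * math.sin(math.pi * t_ms / dt_ms)


def threshold_velocity(
    policy: CompensationPolicy, ecc_deg: float, state: CompensationState
) -> float:
    """Experiment-1 rule: constant velocity for peripheral disks in-window."""
    if ecc_deg > policy.r_th_deg and state.t_since_event_ms <= policy.dt_ms:
        return policy.delta_theta_deg_per_s
    return 0.0


def policy_velocity(
    policy: CompensationPolicy, ecc_deg: float, state: CompensationState
) -> float:
    """Compensation angular velocity (deg/s, illusory-motion frame).

    O -> 0; A -> c*ecc (continuous); B -> c*f(t); C -> c*ecc*f(t);
    U -> c; EXP1_THRESHOLD and EXP2_PULSE as their dedicated rules.
    Before the first event (t = inf) the clamped components vanish, so B
    contributes ``c*constant`` and C ``c*ecc*constant``.
    """
    if ecc_deg < 0:
        raise ValueError("eccentricity must be non-negative")
    k = policy.kind
    t = state.t_since_event_ms
    if k == "O":
        return 0.0
    if k == "A":
        return policy.c * ecc_deg
    if k == "B":
        return policy.c * f_eval(policy.temporal, t if math.isfinite(t) else math.inf)
    if k == "C":
        return policy.c * ecc_deg * f_eval(policy.temporal, t)
    if k == "U":
        return policy.c
    if k == "EXP1_THRESHOLD":
        return threshold_velocity(policy, ecc_deg, state)
    if k == "EXP2_PULSE":
        if math.isinf(t):
            return pulse_velocity(policy.pulse_amplitude_deg_per_s, policy.dt_ms, 0.0) if math.isinf(policy.dt_ms) else 0.0
        return pulse_velocity(policy.pulse_amplitude_deg_per_s, policy.dt_ms, t)
    raise ValueError(f"unknown policy kind: {k!r}")


def advance(
    layout: StimulusLayout,
    policy: CompensationPolicy,
    state: CompensationState,
    events_in_tick,
    dt_ms: float,
    eye_px: tuple[float, float],
) -> StimulusLayout:
    """Advance the closed loop by one display tick, mutating ``state``.

    If any event occurred this tick the elapsed-time clock is reset
    *before* velocities are evaluated, matching the rule that the clock
    restarts on every large eye movement.  Each disk then rotates by its
    policy velocity (mapped from the illusory frame to the screen frame
    by the disk's pattern direction) times the actual tick duration.
    """
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    if events_in_tick:
        state.reset()
    else:
        state.tick(dt_ms)
    if policy.kind == "O":
        return layout
    new_disks = []
    for disk in layout.disks:
        ecc = eccentricity_deg(disk, eye_px, layout.geometry)
        v = policy_velocity(policy, ecc, state)
        new_disks.append(disk.rotated(disk.pattern.direction * v * dt_ms / 1000.0))
    return replace(layout, disks=tuple(new_disks))


@dataclass(frozen=True)
class TrialTrace:
    """Per-sample record of one simulated closed-loop trial.

    ``ecc_deg`` and ``v_comp`` have shape (n_samples, n_disks); the
    compensation velocity is in the illusory-motion frame.  ``dt_ms``
    are the actual inter-sample intervals used for integration.
    """

    t_ms: np.ndarray
    dt_ms: np.ndarray
    t_since_event_ms: np.ndarray
    ecc_deg: np.ndarray
    v_comp: np.ndarray
    events: tuple[GazeEvent, ...]

    def net_rotation_deg(self) -> np.ndarray:
        """Integrated physical rotation per disk (illusory frame)."""
        return (self.v_comp * self.dt_ms[:, None] / 1000.0).sum(axis=0)


def elapsed_since_events(t_ms: np.ndarray, event_times_ms) -> np.ndarray:
    """Elapsed time since the most recent event at each sample (inf before)."""
    out = np.full(len(t_ms), math.inf)
    ev = np.sort(np.asarray(list(event_times_ms), dtype=float))
    if len(ev):
        idx = np.searchsorted(ev, t_ms, side="right") - 1
        has = idx >= 0
        out[has] = t_ms[has] - ev[idx[has]]
    return out


def simulate_trial(
    layout: StimulusLayout,
    policy: CompensationPolicy,
    stream: GazeStream,
    detector: DetectorConfig | None = None,
    disks=None,
) -> TrialTrace:
    """Run detector + policy over a gaze stream and record the trace.

    Operates at gaze cadence with dt taken from actual sample spacing.
    During blinks (invalid samples) the last valid eye position is held;
    if the stream starts invalid, the screen center is used.  ``disks``
    optionally restricts the trace to a subset (e.g. one side of the
    two-alternative layout).
    """
    if detector is None:
        detector = DetectorConfig(geometry=layout.geometry)
    if disks is None:
        disks = layout.disks
    events = tuple(detect_events(stream, detector))
    t = stream.t_ms
    n = len(t)
    dt = np.empty(n)
    dt[1:] = np.diff(t)
    dt[0] = dt[1] if n > 1 else 1000.0 / 90.0

    # Held eye position: forward-fill over invalid samples.
    x = stream.x_px.copy()
    y = stream.y_px.copy()
    x[~stream.valid] = np.nan
    y[~stream.valid] = np.nan
    if np.isnan(x[0]):
        x[0] = layout.geometry.width_px / 2.0
        y[0] = layout.geometry.height_px / 2.0
    idx = np.arange(n)
    last = np.maximum.accumulate(np.where(~np.isnan(x), idx, 0))
    x = x[last]
    y = y[last]

    tse = elapsed_since_events(t, [e.onset_ms for e in events])

    geom = layout.geometry
    centers = np.array([d.center_px for d in disks])
    d_px = np.hypot(centers[None, :, 0] - x[:, None], centers[None, :, 1] - y[:, None])
    ecc = np.degrees(np.arctan2(d_px * geom.pixel_pitch_mm, geom.viewing_distance_mm))

    v = _velocity_array(policy, ecc, tse)
    return TrialTrace(t_ms=t, dt_ms=dt, t_since_event_ms=tse, ecc_deg=ecc, v_comp=v, events=events)


def _velocity_array(policy: CompensationPolicy, ecc: np.ndarray, tse: np.ndarray) -> np.ndarray:
    """Vectorized ``policy_velocity`` over (n_samples, n_disks) inputs."""
    k = policy.kind
    if k == "O":
        return np.zeros_like(ecc)
    if k == "A":
        return policy.c * ecc
    finite = np.isfinite(tse)
    if k == "B":
        ft = np.full(len(tse), policy.temporal.constant)
        ft[finite] = f_eval(policy.temporal, tse[finite])
        return np.broadcast_to((policy.c * ft)[:, None], ecc.shape).copy()
    if k == "C":
        ft = np.full(len(tse), policy.temporal.constant)
        ft[finite] = f_eval(policy.temporal, tse[finite])
        return policy.c * ecc * ft[:, None]
    if k == "U":
        return np.full_like(ecc, policy.c)
    if k == "EXP1_THRESHOLD":
        active = (ecc > policy.r_th_deg) & (tse <= policy.dt_ms)[:, None]
        return np.where(active, policy.delta_theta_deg_per_s, 0.0)
    if k == "EXP2_PULSE":
        if math.isinf(policy.dt_ms):
            return np.full_like(ecc, policy.pulse_amplitude_deg_per_s)
        inside = finite & (tse <= policy.dt_ms)
        ft = np.zeros(len(tse))
        ft[inside] = policy.pulse_amplitude_deg_per_s * np.sin(
            np.pi * tse[inside] / policy.dt_ms
        )
        return np.broadcast_to(ft[:, None], ecc.shape).copy()
    raise ValueError(f"unknown policy kind: {k!r}")


def _policy_from_dict(name: str, d: dict) -> CompensationPolicy:
    temporal = DEFAULT_TEMPORAL_FUNCTION
    if "temporal" in d:
        td = d["temporal"]
        temporal = TemporalFunction(
            components=tuple((float(a), float(dt)) for a, dt in td["components"]),
            constant=float(td.get("constant", 0.0)),
        )
    return CompensationPolicy(
        kind=d.get("kind", name),
        c=float(d.get("c", 0.0)),
        r_th_deg=float(d.get("r_th_deg", 8.0)),
        dt_ms=float(d.get("dt_ms", 300.0)),
        delta_theta_deg_per_s=float(d.get("delta_theta_deg_per_s", 0.0)),
        pulse_amplitude_deg_per_s=float(d.get("pulse_amplitude_deg_per_s", 0.0)),
        temporal=temporal,
    )


def load_policies(path) -> dict[str, CompensationPolicy]:
    """Load named policies from a TOML file (``[policies.<name>]`` tables)."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    return {name: _policy_from_dict(name, d) for name, d in doc.get("policies", {}).items()}


def default_policies() -> dict[str, CompensationPolicy]:
    """Bundled defaults carrying the reference parameter set.

    Detection threshold 10.5 deg/s, peripheral threshold 8.0 deg, window
    300 ms, the default temporal profile, and group-mean calibration
    constants c_A=-0.71, c_B=-0.35, c_C=-0.39, c_U=-0.14.
    """
    ref = resources.files("snakescomp").joinpath("data/default_policies.toml")
    with ref.open("rb") as fh:
        doc = tomllib.load(fh)
    return {name: _policy_from_dict(name, d) for name, d in doc["policies"].items()}
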