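"""Seeded synthetic gaze streams with known event ground truth.

The generator emulates a consumer 90 Hz tracker watching an observer who
alternates fixations and saccades over a desk-mounted display.  It is a
statistical emulation, not an ocular-motor model: fixation durations are
gamma-distributed, fixational jitter is white Gaussian noise, saccades
follow a minimum-jerk trajectory with a linear main-sequence duration
rule (duration_ms = 21 + 2.2 * amplitude_deg), and blinks are inserted
as validity gaps at a Poisson rate.  The exact list of injected events
is returned alongside the samples so detector tests never have to
re-infer ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gaze import GazeStream
from .stimulus import DEFAULT_GEOMETRY, DisplayGeometry

__all__ = ["GazeSimConfig", "SimEvent", "generate"]

# Main-sequence approximation for saccade duration.
_SACC_DUR_INTERCEPT_MS = 21.0
_SACC_DUR_SLOPE_MS_PER_DEG = 2.2


@dataclass(frozen=True)
class SimEvent:
    kind: str  # "saccade" | "blink"
    onset_ms: float
    duration_ms: float
    amplitude_deg: float | None = None  # saccades only


@dataclass(frozen=True)
class GazeSimConfig:
    sample_rate_hz: float = 90.0
    fixation_mean_ms: float | None = None  # derived from saccade rate if None
    fixation_shape: float = 4.0
    saccade_amplitude_range_deg: tuple[float, float] = (2.0, 12.0)
    saccade_rate_per_s: float = 1.5
    blink_rate_per_min: float = 10.0
    blink_duration_range_ms: tuple[float, float] = (100.0, 300.0)
    jitter_sd_deg: float = 0.05
    geometry: DisplayGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for name in ("saccade_rate_per_s", "blink_rate_per_min", "jitter_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.saccade_amplitude_range_deg
        if lo < 0 or hi < lo:
            raise ValueError("invalid saccade amplitude range")

    def mean_saccade_duration_ms(self) -> float:
        lo, hi = self.saccade_amplitude_range_deg
        return _SACC_DUR_INTERCEPT_MS + _SACC_DUR_SLOPE_MS_PER_DEG * (lo + hi) / 2.0

    def effective_fixation_mean_ms(self) -> float:
        """Fixation-duration mean making inter-saccade interval 1/rate."""
        if self.fixation_mean_ms is not None:
            return self.fixation_mean_ms
        if self.saccade_rate_per_s <= 0:
            return math.inf
        mean = 1000.0 / self.saccade_rate_per_s - self.mean_saccade_duration_ms()
        if mean <= 0:
            raise ValueError("saccade rate too high for the amplitude range")
        return mean


def _deg_to_px(deg: float, geometry: DisplayGeometry) -> float:
    """Inverse of the eccentricity convention: px = dist*tan(deg)/pitch."""
    return geometry.viewing_distance_mm * math.tan(math.radians(deg)) / geometry.pixel_pitch_mm


def _min_jerk(frac: np.ndarray) -> np.ndarray:
    """Smooth 0->1 displacement profile with zero endpoint velocity."""
    return 10 * frac**3 - 15 * frac**4 + 6 * frac**5


def generate(config: GazeSimConfig, duration_ms: float):
    """Generate ``(GazeStream, [SimEvent, ...])`` for the given duration.

    Fixations and saccades alternate until the clock runs out; the gaze
    point is clipped to the screen rectangle.  Blink gaps are laid down
    independently at the configured Poisson rate and simply mark samples
    invalid (positions during a blink are undefined).
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    fix_mean = config.effective_fixation_mean_ms()
    if config.blink_rate_per_min > 0 and math.isfinite(fix_mean):
        if config.blink_duration_range_ms[0] > fix_mean:
            raise ValueError("blink durations exceed fixation durations")

    rng = np.random.default_rng(config.seed)
    geom = config.geometry
    dt = 1000.0 / config.sample_rate_hz
    t = np.arange(0.0, duration_ms, dt)
    n = len(t)
    x = np.empty(n)
    y = np.empty(n)
    events: list[SimEvent] = []

    margin = 60.0
    lo = np.array([margin, margin])
    hi = np.array([geom.width_px - margin, geom.height_px - margin])
    pos = np.array([geom.width_px / 2.0, geom.height_px / 2.0])

    do_saccades = config.saccade_rate_per_s > 0 and math.isfinite(fix_mean)
    clock = 0.0
    i = 0
    while i < n:
        # Fixation segment.
        if do_saccades:
            fdur = rng.gamma(config.fixation_shape, fix_mean / config.fixation_shape)
        else:
            fdur = math.inf
        fend = clock + fdur
        j = n if not math.isfinite(fend) else int(np.searchsorted(t, fend, side="left"))
        x[i:j] = pos[0]
        y[i:j] = pos[1]
        i = j
        clock = fend
        if i >= n:
            break
        # Saccade segment.
        amp_deg = rng.uniform(*config.saccade_amplitude_range_deg)
        direction = rng.uniform(0.0, 2.0 * math.pi)
        amp_px = _deg_to_px(amp_deg, geom)
        target = pos + amp_px * np.array([math.cos(direction), math.sin(direction)])
        target = np.clip(target, lo, hi)
        sdur = _SACC_DUR_INTERCEPT_MS + _SACC_DUR_SLOPE_MS_PER_DEG * amp_deg
        send = clock + sdur
        k = int(np.searchsorted(t, send, side="left"))
        if k > i:
            frac = np.clip((t[i:k] - clock) / sdur, 0.0, 1.0)
            prof = _min_jerk(frac)
            x[i:k] = pos[0] + (target[0] - pos[0]) * prof
            y[i:k] = pos[1] + (target[1] - pos[1]) * prof
        events.append(SimEvent("saccade", clock, sdur, amp_deg))
        pos = target
        i = k
        clock = send

    # Fixational jitter on every sample (converted at small-angle scale).
    if config.jitter_sd_deg > 0:
        jitter_px = _deg_to_px(config.jitter_sd_deg, geom)
        x += rng.normal(0.0, jitter_px, n)
        y += rng.normal(0.0, jitter_px, n)
    np.clip(x, lo[0], hi[0], out=x)
    np.clip(y, lo[1], hi[1], out=y)

    # Blink gaps (Poisson process, uniform duration).  Overlapping or
    # touching gaps are merged so the ground truth matches one event per
    # contiguous invalid run.
    valid = np.ones(n, dtype=bool)
    if config.blink_rate_per_min > 0:
        intervals: list[list[float]] = []
        bt = 0.0
        mean_gap_ms = 60000.0 / config.blink_rate_per_min
        while True:
            bt += rng.exponential(mean_gap_ms)
            if bt >= duration_ms:
                break
            bdur = rng.uniform(*config.blink_duration_range_ms)
            a = int(np.searchsorted(t, bt, side="left"))
            b = int(np.searchsorted(t, bt + bdur, side="left"))
            if a >= n or b <= a:
                continue
            if intervals and a <= intervals[-1][1]:
                intervals[-1][1] = max(intervals[-1][1], b)
                intervals[-1][3] = max(intervals[-1][3], bt + bdur)
            else:
                intervals.append([a, b, bt, bt + bdur])
        for a, b, t0, t1 in intervals:
            valid[int(a) : int(b)] = False
            events.append(SimEvent("blink", t0, t1 - t0))

    events.sort(key=lambda e: e.onset_ms)
    return GazeStream(t, x, y, valid), events
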