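"""Gaze streams, tracker-log I/O, and large-eye-movement detection.

Compensation is triggered by *large* eye movements only: saccades,
detected as supra-threshold gaze velocity over a two-frame window, and
blinks, detected as runs of invalid tracker samples.  The two-frame rule
(comparing sample ``n`` with sample ``n-2``) trades a little detection
accuracy for real-time responsiveness at the nominal 90 Hz tracker
rate: per-sample differentiation would be noisier and longer averaging
windows would make the feedback loop sluggish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimulus import DEFAULT_GEOMETRY, DisplayGeometry, span_px_to_deg

__all__ = [
    "GazeSample",
    "GazeStream",
    "GazeEvent",
    "DetectorConfig",
    "detect_events",
    "read_gaze_csv",
    "write_gaze_csv",
]

CSV_COLUMNS = ["timestamp_ms", "x_px", "y_px", "valid"]


@dataclass(frozen=True)
class GazeSample:
    t_ms: float
    x_px: float
    y_px: float
    valid: bool = True


class GazeStream:
    """Timestamped 2-D eye-position samples with validity flags.

    Stored internally as parallel numpy arrays; positions of invalid
    samples are NaN and must not be used.  Timestamps must be strictly
    increasing (nominal rate 90 Hz, ~11.1 ms apart).
    """

    def __init__(self, t_ms, x_px, y_px, valid) -> None:
        self.t_ms = np.asarray(t_ms, dtype=float)
        self.x_px = np.asarray(x_px, dtype=float)
        self.y_px = np.asarray(y_px, dtype=float)
        self.valid = np.asarray(valid, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x_px) == len(self.y_px) == len(self.valid) == n):
            raise ValueError("gaze arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_ms)

    def __getitem__(self, i: int) -> GazeSample:
        return GazeSample(
            float(self.t_ms[i]), float(self.x_px[i]), float(self.y_px[i]), bool(self.valid[i])
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, GazeStream):
            return NotImplemented
        if not (
            np.array_equal(self.t_ms, other.t_ms)
            and np.array_equal(self.valid, other.valid)
        ):
            return False
        # Positions of invalid samples are undefined and not compared.
        m = self.valid
        return np.array_equal(self.x_px[m], other.x_px[m]) and np.array_equal(
            self.y_px[m], other.y_px[m]
        )

    @classmethod
    def from_samples(cls, samples) -> "GazeStream":
        samples = list(samples)
        return cls(
            [s.t_ms for s in samples],
            [s.x_px for s in samples],
            [s.y_px for s in samples],
            [s.valid for s in samples],
        )


@dataclass(frozen=True)
class GazeEvent:
    kind: str  # "saccade" | "blink"
    onset_ms: float
    magnitude_deg_per_s: float | None = None  # saccades only


@dataclass(frozen=True)
class DetectorConfig:
    """Two-frame velocity detector settings (threshold default 10.5 deg/s)."""

    velocity_threshold_deg_per_s: float = 10.5
    evaluation_stride_frames: int = 2
    geometry: DisplayGeometry = field(default_factory=lambda: DEFAULT_GEOMETRY)

    def __post_init__(self) -> None:
        if self.velocity_threshold_deg_per_s <= 0:
            raise ValueError("velocity threshold must be positive")
        if self.evaluation_stride_frames < 1:
            raise ValueError("evaluation stride must be >= 1")


def _displacement_deg(dx_px: float, dy_px: float, geometry: DisplayGeometry) -> float:
    """Gaze displacement in visual degrees (per-axis span, Euclidean)."""
    gx = span_px_to_deg(abs(dx_px), geometry)
    gy = span_px_to_deg(abs(dy_px), geometry)
    return math.hypot(gx, gy)


def detect_events(stream: GazeStream, config: DetectorConfig | None = None) -> list[GazeEvent]:
    """Detect saccades and blinks in a gaze stream.

    Every ``stride`` samples (default 2), the displacement between sample
    ``n`` and sample ``n - stride`` is converted to visual degrees and
    divided by the elapsed time; velocities at or above the threshold
    emit a saccade event at ``t(n)``.  Each contiguous run of invalid
    samples emits exactly one blink event at its onset, and evaluations
    touching an invalid sample are skipped (they count only as the
    blink).  Successive supra-threshold evaluations during one physical
    saccade each emit an event; consumers treat events as timer resets,
    so no saccade segmentation is needed.
    """
    if config is None:
        config = DetectorConfig()
    if len(stream) < 3:
        raise ValueError("stream must contain at least 3 samples")

    events: list[GazeEvent] = []
    valid = stream.valid
    # One blink per contiguous invalid run, stamped at the run onset.
    starts = np.flatnonzero(~valid & np.r_[True, valid[:-1]])
    for i in starts:
        events.append(GazeEvent("blink", float(stream.t_ms[i])))

    k = config.evaluation_stride_frames
    for n in range(k, len(stream), k):
        if not (valid[n] and valid[n - k]):
            continue
        dt_s = (stream.t_ms[n] - stream.t_ms[n - k]) / 1000.0
        disp = _displacement_deg(
            stream.x_px[n] - stream.x_px[n - k],
            stream.y_px[n] - stream.y_px[n - k],
            config.geometry,
        )
        v = disp / dt_s
        if v >= config.velocity_threshold_deg_per_s:
            events.append(GazeEvent("saccade", float(stream.t_ms[n]), v))

    events.sort(key=lambda e: e.onset_ms)
    return events


def read_gaze_csv(path) -> GazeStream:
    """Read a tracker log (``timestamp_ms,x_px,y_px,valid``; valid in {0,1}).

    Invalid rows may leave ``x_px``/``y_px`` empty; they are stored as NaN.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze CSV missing columns: {missing}")
    try:
        t = df["timestamp_ms"].astype(float).to_numpy()
        x = pd.to_numeric(df["x_px"], errors="raise").to_numpy(dtype=float)
        y = pd.to_numeric(df["y_px"], errors="raise").to_numpy(dtype=float)
        v = df["valid"].astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparsable gaze CSV {path}: {exc}") from exc
    if not np.all((v == 0) | (v == 1)):
        bad = int(np.flatnonzero((v != 0) & (v != 1))[0])
        raise ValueError(f"gaze CSV row {bad}: valid must be 0 or 1")
    return GazeStream(t, x, y, v.astype(bool))


def write_gaze_csv(stream: GazeStream, path) -> None:
    """Write the gaze CSV dialect; invalid samples get empty x/y fields."""
    x = np.where(stream.valid, stream.x_px, np.nan)
    y = np.where(stream.valid, stream.y_px, np.nan)
    df = pd.DataFrame(
        {
            "timestamp_ms": stream.t_ms,
            "x_px": x,
            "y_px": y,
            "valid": stream.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")
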