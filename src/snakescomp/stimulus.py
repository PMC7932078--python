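"""Rotating-snakes stimulus model and renderer.

The rotating snakes illusion (RSI) is carried by disks tiled with a
repeating four-luminance wedge pattern (black, dark gray, white, light
gray).  A static arrangement of these wedges is perceived as rotating,
most strongly in peripheral vision and just after saccades or blinks.
This module models the disk geometry, the named experimental layouts,
pixel/visual-angle conversion for a fixed-head viewing geometry, and an
analytic (non-anti-aliased) renderer whose output is bit-exact under
rotation by one pattern period.

Screen coordinates follow the raster convention: origin at the top-left
corner, x rightward, y downward, 0-based pixels.  Because y points down,
a mathematically increasing angle ``atan2(dy, dx)`` corresponds to a
clockwise sweep as seen by the viewer, so disk orientations are stored
CW-positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DisplayGeometry",
    "PatternSpec",
    "Disk",
    "StimulusLayout",
    "DEFAULT_GEOMETRY",
    "build_layout",
    "span_px_to_deg",
    "render_frame",
]

#: Default grayscale cycle for clockwise illusory motion: black -> dark
#: gray -> white -> light gray along the direction of perceived motion
#: (the canonical RSI arrangement).
DEFAULT_LEVELS = (0, 63, 255, 191)


@dataclass(frozen=True)
class DisplayGeometry:
    """Fixed-head display geometry.

    The default matches a 1920x1080 panel viewed from 500 mm with a
    0.27675 mm pixel pitch (24-inch 16:9 panel, 531.4 mm visible width)
    and a 30 cd/m^2 background.  The pitch is chosen so that the span
    conversions reproduce 45.1 deg for 1500 px and 28.0 deg for 900 px.
    """

    width_px: int = 1920
    height_px: int = 1080
    pixel_pitch_mm: float = 0.27675
    viewing_distance_mm: float = 500.0
    background_level: int = 128
    background_luminance_cdm2: float = 30.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("display dimensions must be positive")
        if self.pixel_pitch_mm <= 0 or self.viewing_distance_mm <= 0:
            raise ValueError("pixel pitch and viewing distance must be positive")


DEFAULT_GEOMETRY = DisplayGeometry()


@dataclass(frozen=True)
class PatternSpec:
    """Repeating four-luminance wedge pattern of one RSI disk.

    ``segment_arc_deg`` is the arc of a single wedge; the four ``levels``
    repeat around the disk, so the pattern period is ``4 *
    segment_arc_deg`` (36 deg at the default 9-deg arc, i.e. 40 wedges,
    10 color cycles).  ``direction`` is +1 for clockwise illusory motion
    and -1 for the mirrored, counterclockwise arrangement.
    """

    segment_arc_deg: float = 9.0
    levels: tuple[int, int, int, int] = DEFAULT_LEVELS
    direction: int = +1

    def __post_init__(self) -> None:
        n = 360.0 / self.segment_arc_deg
        if abs(n - round(n)) > 1e-9:
            raise ValueError("segment_arc_deg must divide 360 evenly")
        if sorted(self.levels) != [0, 63, 191, 255]:
            raise ValueError("levels must be a cyclic order of {0, 63, 191, 255}")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 (CW) or -1 (CCW)")

    @property
    def n_segments(self) -> int:
        return round(360.0 / self.segment_arc_deg)

    @property
    def period_deg(self) -> float:
        """Angular period of the full four-level cycle."""
        return self.segment_arc_deg * len(self.levels)


@dataclass(frozen=True)
class Disk:
    center_px: tuple[float, float]
    diameter_px: float = 150.0
    pattern: PatternSpec = field(default_factory=PatternSpec)
    orientation_deg: float = 0.0  # physical rotation, CW-positive

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError("diameter_px must be positive")
        object.__setattr__(self, "orientation_deg", self.orientation_deg % 360.0)

    def rotated(self, delta_deg: float) -> "Disk":
        return replace(self, orientation_deg=(self.orientation_deg + delta_deg) % 360.0)


@dataclass(frozen=True)
class StimulusLayout:
    disks: tuple[Disk, ...]
    geometry: DisplayGeometry = DEFAULT_GEOMETRY
    name: str = ""
    side_labels: tuple[str, ...] | None = None  # "left"/"right" per disk

    def disks_on(self, side: str) -> tuple[Disk, ...]:
        if self.side_labels is None:
            raise ValueError("layout has no side labels")
        return tuple(d for d, s in zip(self.disks, self.side_labels) if s == side)

    def with_orientations(self, orientations_deg) -> "StimulusLayout":
        disks = tuple(
            replace(d, orientation_deg=float(o) % 360.0)
            for d, o in zip(self.disks, orientations_deg)
        )
        return replace(self, disks=disks)


def build_layout(
    name: str, direction: int = +1, geometry: DisplayGeometry = DEFAULT_GEOMETRY
) -> StimulusLayout:
    """Build a named experimental disk layout with all orientations at 0.

    ``"exp1_pair"`` is the two-alternative arrangement: two 2x3 sets of
    150-px disks, inner columns 300 px and outer columns 600 px from the
    screen center, rows at 0 and +/-300 px.  ``"exp2_grid"`` is the single
    4x3 grid with columns at +/-150 and +/-450 px and the same rows, so
    neighboring centers sit 300 px apart and the disks circumscribe each
    other.
    """
    cx = geometry.width_px / 2.0
    cy = geometry.height_px / 2.0
    pattern = PatternSpec(direction=direction)
    rows = (-300.0, 0.0, 300.0)
    if name == "exp1_pair":
        cols = (-600.0, -300.0, 300.0, 600.0)
        disks = []
        sides = []
        for dx in cols:
            for dy in rows:
                disks.append(Disk(center_px=(cx + dx, cy + dy), pattern=pattern))
                sides.append("left" if dx < 0 else "right")
        return StimulusLayout(
            disks=tuple(disks), geometry=geometry, name=name, side_labels=tuple(sides)
        )
    if name == "exp2_grid":
        cols = (-450.0, -150.0, 150.0, 450.0)
        disks = tuple(
            Disk(center_px=(cx + dx, cy + dy), pattern=pattern)
            for dx in cols
            for dy in rows
        )
        return StimulusLayout(disks=disks, geometry=geometry, name=name)
    raise ValueError(f"unknown layout name: {name!r}")


def span_px_to_deg(extent_px: float, geometry: DisplayGeometry = DEFAULT_GEOMETRY) -> float:
    """Convert an on-screen extent to its full visual angle in degrees.

    The extent is taken as centered on the line of sight, so the angle is
    ``2 * atan((extent * pitch / 2) / distance)``.
    """
    if extent_px < 0:
        raise ValueError("extent_px must be non-negative")
    half_mm = extent_px * geometry.pixel_pitch_mm / 2.0
    return math.degrees(2.0 * math.atan2(half_mm, geometry.viewing_distance_mm))


def render_frame(layout: StimulusLayout) -> np.ndarray:
    """Render a layout to an 8-bit grayscale raster.

    Each pixel inside a disk takes the level of its angular wedge,
    evaluated analytically in polar coordinates around the disk center
    (nearest lookup, no anti-aliasing); everything else is the background
    level.  The orientation is reduced modulo the pattern period before
    the lookup, which makes rotation by a whole period bit-exact.
    """
    geom = layout.geometry
    frame = np.full((geom.height_px, geom.width_px), geom.background_level, dtype=np.uint8)
    painted = np.zeros_like(frame, dtype=bool)
    for disk in layout.disks:
        x0, y0 = disk.center_px
        r = disk.diameter_px / 2.0
        xmin, xmax = int(math.floor(x0 - r)), int(math.ceil(x0 + r))
        ymin, ymax = int(math.floor(y0 - r)), int(math.ceil(y0 + r))
        if xmin < 0 or ymin < 0 or xmax >= geom.width_px or ymax >= geom.height_px:
            raise ValueError("disk does not fit within the raster bounds")
        ys, xs = np.mgrid[ymin : ymax + 1, xmin : xmax + 1]
        dx = xs - x0
        dy = ys - y0
        inside = dx * dx + dy * dy <= r * r
        if np.any(painted[ymin : ymax + 1, xmin : xmax + 1] & inside):
            raise ValueError("overlapping disks are not supported")
        pat = disk.pattern
        # CW-positive screen angle; fmod keeps period reduction exact.
        phi = np.degrees(np.arctan2(dy, dx))
        theta = math.fmod(disk.orientation_deg, pat.period_deg)
        u = np.mod(pat.direction * (phi - theta), 360.0)
        idx = (u // pat.segment_arc_deg).astype(np.intp) % len(pat.levels)
        block = frame[ymin : ymax + 1, xmin : xmax + 1]
        block[inside] = np.asarray(pat.levels, dtype=np.uint8)[idx[inside]]
        painted[ymin : ymax + 1, xmin : xmax + 1] |= inside
    return frame
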