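"""Flat-panel display geometry and view-angle correction.

A tethered fly sits a short distance ``d`` in front of a flat screen.  To make a
flat panel imitate a cylindrical display, on-screen features must be drawn wider
toward the screen edges so that equal spans of *visual angle* (azimuth) map to
unequal physical widths.  The mapping is the gnomonic projection for a fronto-
parallel plane:

    x = d * tan(azimuth)

where ``x`` is the horizontal offset from the screen center (mm) and azimuth is
measured from the straight-ahead direction, positive toward the fly's right.
Elevation uses the same formula on the vertical axis; there is no cylindrical
curvature in elevation.

All public interfaces take and return degrees; radians are used internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DisplayGeometry",
    "VirtualCylinder",
    "azimuth_to_screen_x",
    "screen_x_to_azimuth",
    "arc_screen_width",
    "visible_field",
]


@dataclass(frozen=True)
class DisplayGeometry:
    """Physical and viewing parameters of the stimulus panel.

    Defaults describe a 7-inch 1024 x 600 tablet panel (151.8 x 83.4 mm active
    area) refreshed at 60 Hz, viewed from 35 mm — the span seen by the animal is
    then ~130 deg in azimuth and ~100 deg in elevation.
    """

    physical_width_mm: float = 151.8
    physical_height_mm: float = 83.4
    px_width: int = 1024
    px_height: int = 600
    viewer_distance_mm: float = 35.0
    refresh_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in ("physical_width_mm", "physical_height_mm", "viewer_distance_mm",
                     "refresh_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.px_width < 1 or self.px_height < 1:
            raise ValueError("pixel counts must be >= 1")

    @property
    def pixel_pitch_mm(self) -> float:
        """Horizontal pixel pitch; constant across the panel."""
        return self.physical_width_mm / self.px_width

    @property
    def frame_interval_ms(self) -> float:
        """Nominal inter-frame interval (~17 ms at 60 Hz)."""
        return 1000.0 / self.refresh_rate_hz

    def column_x_mm(self) -> np.ndarray:
        """Physical x offset of each pixel-column center from screen center."""
        cols = np.arange(self.px_width) + 0.5
        return cols * self.pixel_pitch_mm - self.physical_width_mm / 2.0

    def column_azimuths_deg(self) -> np.ndarray:
        """Azimuth of each pixel-column center, increasing left-to-right."""
        return screen_x_to_azimuth(self.column_x_mm(), self)


@dataclass(frozen=True)
class VirtualCylinder:
    """A virtual cylinder of luminance segments centered on the viewer.

    The cylinder diameter (default 305 mm, the size of a typical LED arena) is
    cosmetic for an on-axis viewer: pixel luminance depends only on the viewing
    *angle*, never on the chord length, so rendering is diameter-invariant.

    Segments are ``(azimuth_start_deg, azimuth_end_deg, luminance)`` tuples with
    non-overlapping azimuth ranges and luminance in [0, 1].
    """

    diameter_mm: float = 305.0
    segments: tuple[tuple[float, float, float], ...] = field(default_factory=tuple)
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")
        segs = tuple(tuple(map(float, s)) for s in self.segments)
        object.__setattr__(self, "segments", segs)
        for lo, hi, lum in segs:
            if hi <= lo:
                raise ValueError(f"segment ({lo}, {hi}) has non-positive extent")
            if not 0.0 <= lum <= 1.0:
                raise ValueError(f"luminance {lum} outside [0, 1]")
        ordered = sorted(segs)
        for (_, hi_a, _), (lo_b, _, _) in zip(ordered, ordered[1:]):
            if lo_b < hi_a:
                raise ValueError("segments overlap in azimuth")

    def luminance(self, azimuth_deg) -> np.ndarray:
        """Luminance seen along the given azimuth(s)."""
        az = np.asarray(azimuth_deg, dtype=float)
        out = np.full(az.shape, self.background)
        for lo, hi, lum in self.segments:
            out = np.where((az >= lo) & (az < hi), lum, out)
        return out


def azimuth_to_screen_x(azimuth_deg, geom: DisplayGeometry):
    """Map azimuth (deg) to horizontal offset (mm) from screen center.

    Positive azimuth (fly's right) maps to positive offset.  Only defined for
    ``|azimuth| < 90`` — directions at or behind the screen plane do not
    intersect it.
    """
    az = np.asarray(azimuth_deg, dtype=float)
    if np.any(np.abs(az) >= 90.0):
        raise ValueError("azimuth must satisfy |azimuth| < 90 deg for a flat screen")
    x = geom.viewer_distance_mm * np.tan(np.deg2rad(az))
    return float(x) if np.isscalar(azimuth_deg) else x


def screen_x_to_azimuth(x_mm, geom: DisplayGeometry):
    """Inverse projection: horizontal offset (mm) to azimuth (deg)."""
    x = np.asarray(x_mm, dtype=float)
    az = np.rad2deg(np.arctan2(x, geom.viewer_distance_mm))
    return float(az) if np.isscalar(x_mm) else az


def arc_screen_width(az_lo_deg: float, az_hi_deg: float, geom: DisplayGeometry) -> float:
    """Physical on-screen width (mm) of the azimuth interval [az_lo, az_hi].

    Because of the tangent projection, arcs of equal angular span are physically
    wider near the screen edges than at its center.
    """
    if az_hi_deg <= az_lo_deg:
        raise ValueError(f"need az_hi > az_lo, got [{az_lo_deg}, {az_hi_deg}]")
    return azimuth_to_screen_x(az_hi_deg, geom) - azimuth_to_screen_x(az_lo_deg, geom)


def visible_field(geom: DisplayGeometry) -> tuple[float, float]:
    """(azimuth span, elevation span) in degrees subtended by the panel."""
    d = geom.viewer_distance_mm
    az = 2.0 * np.rad2deg(np.arctan2(geom.physical_width_mm / 2.0, d))
    el = 2.0 * np.rad2deg(np.arctan2(geom.physical_height_mm / 2.0, d))
    return float(az), float(el)
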