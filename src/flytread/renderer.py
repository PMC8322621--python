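"""Headless rasterization of stimuli through the display geometry.

Renders one luminance value per pixel column (the stimuli are vertical bars, so
a single scanline describes the whole frame), stacks scanlines into space-time
diagrams, simulates a photodiode patch on the panel, and computes a signed
net-motion index from the 2-D spatiotemporal spectrum.  The latter makes the
display-refresh aliasing control quantitative: a grating whose temporal
frequency equals half the refresh rate advances half a period per frame, which
is indistinguishable from counterphase flicker and carries no net motion.

Rendering samples pixel-column centers with no anti-aliasing (a square-wave
pattern on an LCD); frames are zero-order-hold between refreshes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .geometry import DisplayGeometry, VirtualCylinder
from .stimuli import TrialSpec, luminance_at

__all__ = [
    "SpaceTimeDiagram",
    "PixelPatch",
    "render_scanline",
    "space_time",
    "photodiode_trace",
    "dominant_frequency",
    "net_motion_index",
    "default_photodiode_patch",
    "diagram_to_csv",
    "diagram_to_png",
]


@dataclass(frozen=True)
class SpaceTimeDiagram:
    """Luminance matrix indexed by (frame, pixel column).

    Plotted with the spatial axis right-to-left and time top-to-bottom,
    clockwise motion appears as tilts going down and to the left.
    """

    matrix: np.ndarray            # (n_frames, n_columns), values in [0, 1]
    frame_times_s: np.ndarray     # (n_frames,)
    column_azimuths_deg: np.ndarray  # (n_columns,)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.frame_times_s), len(self.column_azimuths_deg)):
            raise ValueError("matrix shape must be (n_frames, n_columns)")


@dataclass(frozen=True)
class PixelPatch:
    """Rectangle of pixels: origin (column, row) plus size, in px."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("patch must be at least 1x1 px")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("patch origin must be non-negative")


def render_scanline(stimulus, geom: DisplayGeometry, t_s: float = 0.0,
                    supersample: int = 1) -> np.ndarray:
    """Per-pixel-column luminance of one frame.

    ``stimulus`` is a :class:`~flytread.stimuli.TrialSpec`, a bare stimulus
    spec, or a :class:`~flytread.geometry.VirtualCylinder`.  With
    ``supersample > 1`` each column averages that many sub-pixel samples
    (useful to model sensor-scale spatial averaging; default none).
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    if supersample == 1:
        az = geom.column_azimuths_deg()
    else:
        ss = (np.arange(geom.px_width * supersample) + 0.5) / supersample
        x = ss * geom.pixel_pitch_mm - geom.physical_width_mm / 2.0
        from .geometry import screen_x_to_azimuth
        az = screen_x_to_azimuth(x, geom)
    if isinstance(stimulus, VirtualCylinder):
        lum = stimulus.luminance(az)
    else:
        lum = luminance_at(stimulus, az, t_s)
    if supersample > 1:
        lum = lum.reshape(geom.px_width, supersample).mean(axis=1)
    return np.asarray(lum, dtype=float)


def space_time(trial: TrialSpec, geom: DisplayGeometry,
               n_columns: int | None = None) -> SpaceTimeDiagram:
    """Stack scanlines over every display frame of a trial (pre/motion/post).

    ``n_columns`` subsamples the panel columns evenly (default: all columns).
    """
    duration_s = trial.duration_ms / 1000.0
    if not math.isfinite(duration_s):
        raise ValueError("trial duration must be finite")
    n_frames = math.ceil(duration_s * geom.refresh_rate_hz)
    t = np.arange(n_frames) / geom.refresh_rate_hz
    az = geom.column_azimuths_deg()
    if n_columns is not None:
        idx = np.linspace(0, geom.px_width - 1, n_columns).round().astype(int)
        az = az[idx]
    matrix = luminance_at(trial, az[None, :], t[:, None])
    return SpaceTimeDiagram(np.asarray(matrix, dtype=float), t, az)


def default_photodiode_patch(geom: DisplayGeometry, size_mm: float = 5.0,
                             margin_mm: float = 2.0) -> PixelPatch:
    """A ~5 mm square patch near the right display edge (sensor position)."""
    size_px = max(1, round(size_mm / geom.pixel_pitch_mm))
    x0 = geom.px_width - size_px - max(0, round(margin_mm / geom.pixel_pitch_mm))
    y0 = (geom.px_height - size_px) // 2
    return PixelPatch(max(0, x0), max(0, y0), size_px, min(size_px, geom.px_height))


def photodiode_trace(trial: TrialSpec, geom: DisplayGeometry,
                     patch: PixelPatch | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Mean luminance over a pixel patch for every display frame.

    Returns ``(t_s, luminance)``.  The stimuli are vertically uniform, so the
    patch average reduces to a mean over its pixel columns; the patch must lie
    within the panel.
    """
    if patch is None:
        patch = default_photodiode_patch(geom)
    if (patch.x0 + patch.width > geom.px_width
            or patch.y0 + patch.height > geom.px_height):
        raise ValueError(f"patch {patch} extends outside the {geom.px_width}x"
                         f"{geom.px_height} px panel")
    diagram = space_time(trial, geom)
    cols = slice(patch.x0, patch.x0 + patch.width)
    return diagram.frame_times_s, diagram.matrix[:, cols].mean(axis=1)


def dominant_frequency(series: np.ndarray, fs: float) -> float:
    """Frequency (Hz) of the periodogram peak, DC excluded.

    Returns NaN for a (numerically) constant series, which has no dominant
    frequency.
    """
    series = np.asarray(series, dtype=float)
    if np.var(series) < 1e-12 * (1.0 + np.mean(series) ** 2):
        return float("nan")
    freqs, power = _signal.periodogram(series, fs=fs, detrend="constant")
    nz = freqs > 0
    return float(freqs[nz][np.argmax(power[nz])])


def net_motion_index(diagram: SpaceTimeDiagram) -> float:
    """Signed directional energy of a space-time diagram; positive = CW.

    Difference of the opponent quadrant energies of the 2-D spectrum,
    normalized by their sum to [-1, 1].  DC rows/columns and (for even sizes)
    the Nyquist row/column are excluded: energy exactly at the temporal Nyquist
    — the refresh-aliasing flicker case — has no direction.  Returns 0 when no
    directional energy remains (static patterns, pure flicker).
    """
    m = np.asarray(diagram.matrix, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    m = m - m.mean()
    spec = np.abs(np.fft.fft2(m)) ** 2
    ft = np.fft.fftfreq(m.shape[0])[:, None]  # temporal frequency (cycles/frame)
    fx = np.fft.fftfreq(m.shape[1])[None, :]  # spatial frequency (cycles/column)
    valid = (ft != 0) & (fx != 0) & (np.abs(ft) != 0.5) & (np.abs(fx) != 0.5)
    # a pattern moving toward +azimuth (CW) carries energy where ft and fx
    # have opposite signs under the forward-DFT sign convention
    cw = float(spec[valid & (ft * fx < 0)].sum())
    ccw = float(spec[valid & (ft * fx > 0)].sum())
    total = cw + ccw
    if total <= 1e-9 * max(spec.sum(), 1.0):
        return 0.0
    return (cw - ccw) / total


def diagram_to_csv(diagram: SpaceTimeDiagram, path) -> None:
    """Write a diagram as CSV: header of column azimuths, then t_s + one row/frame."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["t_s"] + [f"{a:.6g}" for a in diagram.column_azimuths_deg])
        for t, row in zip(diagram.frame_times_s, diagram.matrix):
            w.writerow([f"{t:.9g}"] + [f"{v:.6g}" for v in row])


def diagram_to_png(diagram: SpaceTimeDiagram, path) -> None:
    """Render a diagram to a grayscale PNG (space right-to-left, time downward)."""
    import matplotlib.image as mpimg
    mpimg.imsave(path, diagram.matrix[:, ::-1], cmap="gray", vmin=0.0, vmax=1.0)
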