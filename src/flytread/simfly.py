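"""A synthetic walking fly with a temporal-frequency-tuned optomotor response.

The simulator stands in for the tethered animal so the entire stimulus →
treadmill → analysis pipeline can be exercised without hardware.  The fly walks
forward at ~10 mm/s and turns syn-directionally with wide-field motion.  Its
turning gain is a log-Gaussian function of the stimulus temporal frequency —
the minimal unimodal model of the well-known TF tuning of insect motion vision
(most sensitive near a few Hz, less sensitive above and below).  The analysis
pipeline makes no use of this form; it only computes empirical means.

Two deliberate couplings to the *rendered* stimulus, not the nominal one:

* The directional drive for a grating condition is taken from the sign of the
  net-motion index of its rendered space-time diagram.  A grating whose TF is
  half the display refresh rate renders as pure flicker, so the synthetic fly
  correctly shows no mean turning for that control condition — a fly cannot
  follow motion that is not there.
* Grating drive is attenuated by Gaussian ommatidial blur (acceptance angle
  ~5 deg), so fine spatial periods (λ <= 10 deg) evoke weak or no turning, as
  real flies show.

Output is emitted as valid FicTrac-format frames at the camera rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .fictrac import FicTracData
from .geometry import DisplayGeometry
from .stimuli import (BarSweepSpec, ClosedLoopSpec, GratingSpec, TrialSpec,
                      temporal_frequency)

__all__ = ["FlyModel", "optomotor_gain", "simulate_fly", "effective_direction"]


@dataclass(frozen=True)
class FlyModel:
    """Parameters of the synthetic optomotor fly.

    ``peak_gain_dps`` is the mean turning velocity at the tuning optimum;
    ``tuning_log_width`` is the log-Gaussian width in ln(TF) units;
    ``response_latency_ms`` shifts the sensory drive in time;
    ``motor_noise_sd_dps`` is white yaw-velocity noise per camera frame.
    """

    peak_gain_dps: float = 50.0
    optimal_tf_hz: float = 4.0
    tuning_log_width: float = 1.5
    response_latency_ms: float = 50.0
    motor_noise_sd_dps: float = 25.0
    forward_speed_mean_mm_s: float = 10.0
    forward_speed_sd_mm_s: float = 2.0
    camera_rate_hz: float = 180.0
    seed: int = 0
    ommatidial_angle_deg: float = 5.0   # acceptance angle for spatial blur
    bar_midline_gating: bool = False    # optional: respond only to progressive motion

    def __post_init__(self) -> None:
        if self.peak_gain_dps < 0:
            raise ValueError("peak_gain_dps must be >= 0")
        if self.optimal_tf_hz <= 0:
            raise ValueError("optimal_tf_hz must be > 0")
        if self.camera_rate_hz <= 0:
            raise ValueError("camera_rate_hz must be > 0")


def optomotor_gain(fly: FlyModel, tf_hz) -> np.ndarray | float:
    """Turning gain (deg/s) at temporal frequency ``tf_hz``; 0 at tf = 0.

    g(tf) = peak_gain * exp(-(ln(tf / tf_opt))^2 / (2 w^2))
    """
    tf = np.asarray(tf_hz, dtype=float)
    out = np.zeros(tf.shape)
    pos = tf > 0
    with np.errstate(divide="ignore"):
        lg = np.log(np.where(pos, tf, 1.0) / fly.optimal_tf_hz)
    out = np.where(pos, fly.peak_gain_dps
                   * np.exp(-lg**2 / (2.0 * fly.tuning_log_width**2)), 0.0)
    return float(out) if np.isscalar(tf_hz) else out


def _acuity_attenuation(fly: FlyModel, spatial_period_deg: float) -> float:
    """Contrast attenuation of a grating by Gaussian ommatidial blur.

    A Gaussian acceptance function of half-width Δρ attenuates a sinusoid of
    spatial frequency 1/λ by exp(-(pi Δρ / λ)^2 / (4 ln 2)); applied to the
    square-wave fundamental.
    """
    if fly.ommatidial_angle_deg <= 0:
        return 1.0
    x = math.pi * fly.ommatidial_angle_deg / spatial_period_deg
    return math.exp(-x * x / (4.0 * math.log(2.0)))


@lru_cache(maxsize=256)
def _rendered_direction(spatial_period_deg: float, omega_dps: float,
                        refresh_rate_hz: float, viewer_distance_mm: float,
                        physical_width_mm: float) -> float:
    """Sign of the net-motion index of the rendered grating (0 for flicker)."""
    from .renderer import net_motion_index, space_time
    geom = DisplayGeometry(physical_width_mm=physical_width_mm,
                           viewer_distance_mm=viewer_distance_mm,
                           refresh_rate_hz=refresh_rate_hz)
    trial = TrialSpec.for_grating(GratingSpec(spatial_period_deg, omega_dps), "probe",
                                  pre_ms=0.0, motion_ms=1000.0, post_ms=0.0)
    idx = net_motion_index(space_time(trial, geom, n_columns=128))
    if abs(idx) < 1e-6:
        return 0.0
    return math.copysign(1.0, idx)


def effective_direction(spec: GratingSpec, geom: DisplayGeometry) -> float:
    """Direction (+1 CW, -1 CCW, 0 none) of the grating as actually displayed."""
    if spec.angular_velocity_dps == 0:
        return 0.0
    return _rendered_direction(spec.spatial_period_deg, spec.angular_velocity_dps,
                               geom.refresh_rate_hz, geom.viewer_distance_mm,
                               geom.physical_width_mm)


def _bar_effective_tf(spec: BarSweepSpec) -> float:
    """TF of a grating whose bars match the bar width: |omega| / (2 * width)."""
    return abs(spec.angular_velocity_dps) / (2.0 * spec.bar_width_deg)


def simulate_fly(fly: FlyModel, schedule, geom: DisplayGeometry,
                 seed: int | None = None) -> FicTracData:
    """Simulate treadmill output for a scheduled experiment.

    ``schedule`` is the list of :class:`~flytread.engine.ScheduledTrial` laid
    out by the engine.  At each camera frame the heading increments by
    ``(drive + noise) * dt`` where the drive, evaluated at ``t - latency``, is

    * gratings: rendered direction x TF-tuned gain x acuity attenuation during
      the motion epoch;
    * bars: direction x gain at the bar's effective TF while the bar overlaps
      the visible field (optionally only after it crosses the midline);
    * otherwise (pre/post epochs, closed-loop trials, startup): zero mean.

    Deterministic for a fixed seed (default: the fly's own seed).
    """
    if not schedule:
        raise ValueError("schedule must be non-empty")
    rng = np.random.default_rng(fly.seed if seed is None else seed)
    dt = 1.0 / fly.camera_rate_hz
    total_s = schedule[-1].t_end_ms / 1000.0
    n = math.ceil(total_s * fly.camera_rate_hz)
    t = np.arange(1, n + 1) * dt                 # time of each camera frame
    t_eval = t - fly.response_latency_ms / 1000.0  # sensory delay

    drive = np.zeros(n)
    half_visible = visible_half_span_deg(geom)
    for st in schedule:
        stim = st.trial.stimulus
        if isinstance(stim, ClosedLoopSpec):
            continue  # no open-loop drive model for closed-loop trials
        on = st.t_motion_on_ms / 1000.0
        off = st.t_motion_off_ms / 1000.0
        mask = (t_eval >= on) & (t_eval < off)
        if not mask.any():
            continue
        if isinstance(stim, GratingSpec):
            direction = effective_direction(stim, geom)
            gain = optomotor_gain(fly, temporal_frequency(stim))
            drive[mask] = direction * gain * _acuity_attenuation(
                fly, stim.spatial_period_deg)
        elif isinstance(stim, BarSweepSpec):
            center = stim.center_deg(t_eval[mask] - on)
            visible = np.abs(center) < half_visible + stim.bar_width_deg / 2.0
            if fly.bar_midline_gating:
                visible &= center * stim.angular_velocity_dps > 0
            sgn = math.copysign(1.0, stim.angular_velocity_dps)
            gain = optomotor_gain(fly, _bar_effective_tf(stim))
            drive[mask] = np.where(visible, sgn * gain, 0.0)

    yaw_dps = drive
    if fly.motor_noise_sd_dps > 0:
        yaw_dps = yaw_dps + rng.normal(0.0, fly.motor_noise_sd_dps, n)
    heading = np.mod(np.cumsum(np.deg2rad(yaw_dps) * dt), 2.0 * np.pi)

    speed_mm_s = np.clip(
        rng.normal(fly.forward_speed_mean_mm_s, fly.forward_speed_sd_mm_s, n)
        if fly.forward_speed_sd_mm_s > 0
        else np.full(n, fly.forward_speed_mean_mm_s), 0.0, None)
    from .fictrac import SphereSpec
    sphere = SphereSpec()
    speed_rad_frame = speed_mm_s * dt / sphere.radius_mm

    return FicTracData.from_components(
        heading_rad=heading,
        movement_speed_rad_per_frame=speed_rad_frame,
        delta_timestamp_s=np.full(n, dt))


def visible_half_span_deg(geom: DisplayGeometry) -> float:
    """Half the azimuth span covered by the panel."""
    from .geometry import visible_field
    return visible_field(geom)[0] / 2.0
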