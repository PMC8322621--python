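"""Stimulus definitions and experimental protocols.

Three protocol families probe the optomotor turning response of a walking fly:

* **temporal** — square-wave gratings of spatial period λ = 90 deg moving at one
  of seven angular speeds in each direction, sampling temporal frequencies
  (TF = |ω|/λ) of 0.25, 1, 2, 4, 7.5, 15 and 30 Hz (14 conditions).  The 30 Hz
  condition is a control: at half the 60 Hz display refresh it is pure flicker.
* **spatial** — gratings of spatial period λ in {5, 10, 20, 30, 60, 90, 120} deg,
  all moving at TF = 7.5 Hz, in each direction (14 conditions; angular speeds
  span 37.5–900 deg/s).
* **bar** — a single bright 45 deg bar sweeping once across the screen at one of
  six speeds in each direction (12 conditions; durations 0.13–7.8 s).

Each open-loop trial shows the pattern stationary for 500 ms, moving for 3 s
(bars: for one sweep), then stationary again for 500 ms.  Conditions are
presented in randomly ordered blocks, repeated 6 times, optionally interleaved
with closed-loop trials; a 10 s startup delay precedes the first trial.

Sign convention: azimuth 0 is straight ahead, positive to the fly's right;
positive ω means clockwise (CW) motion, i.e. the pattern moves toward positive
azimuth (rightward on the retina).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GratingSpec",
    "BarSweepSpec",
    "ClosedLoopSpec",
    "TrialSpec",
    "Protocol",
    "temporal_frequency",
    "luminance_at",
    "sweep_duration",
    "build_protocol",
    "randomize_blocks",
    "protocol_to_yaml",
    "protocol_from_yaml",
    "trials_to_frame",
    "TEMPORAL_SPEEDS_DPS",
    "SPATIAL_PERIODS_DEG",
    "BAR_SPEEDS_DPS",
    "DEFAULT_SWEEP_SPAN_DEG",
]

#: Angular speeds (deg/s) of the temporal-frequency protocol (one direction).
TEMPORAL_SPEEDS_DPS = (22.5, 90.0, 180.0, 360.0, 675.0, 1350.0, 2700.0)
#: Spatial periods (deg) of the spatial-period protocol, all at TF = 7.5 Hz.
SPATIAL_PERIODS_DEG = (5.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0)
#: Bar sweep speeds (deg/s, one direction).
BAR_SPEEDS_DPS = (22.5, 90.0, 180.0, 360.0, 675.0, 1350.0)
#: Default sweep span: visible azimuth span (130.5 deg) + bar width (45 deg),
#: so the bar starts fully off one screen edge and ends fully off the other.
DEFAULT_SWEEP_SPAN_DEG = 175.5


@dataclass(frozen=True)
class GratingSpec:
    """Square-wave grating: half of each period bright, half dark."""

    spatial_period_deg: float = 90.0
    angular_velocity_dps: float = 0.0  # signed; + = CW (toward positive azimuth)
    bright_luminance: float = 1.0
    dark_luminance: float = 0.0
    phase0_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.spatial_period_deg <= 0:
            raise ValueError("spatial_period_deg must be > 0")
        for name in ("bright_luminance", "dark_luminance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class BarSweepSpec:
    """A single bright vertical bar sweeping once across the visual field."""

    bar_width_deg: float = 45.0
    bar_luminance: float = 1.0
    background_luminance: float = 0.0  # screen is otherwise dark
    angular_velocity_dps: float = 0.0  # signed; + = CW
    sweep_span_deg: float = DEFAULT_SWEEP_SPAN_DEG

    def __post_init__(self) -> None:
        if self.bar_width_deg <= 0:
            raise ValueError("bar_width_deg must be > 0")
        if self.sweep_span_deg < self.bar_width_deg:
            raise ValueError("sweep_span_deg must be >= bar_width_deg")
        for name in ("bar_luminance", "background_luminance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def center_deg(self, t_motion_s: float):
        """Bar-center azimuth as a function of motion time (vectorizable).

        The bar starts centered at -sign(ω)·span/2 (fully off one edge) and
        traverses to +sign(ω)·span/2.
        """
        sgn = np.sign(self.angular_velocity_dps) or 1.0
        return -sgn * self.sweep_span_deg / 2.0 + self.angular_velocity_dps * np.asarray(
            t_motion_s, dtype=float)


@dataclass(frozen=True)
class ClosedLoopSpec:
    """Closed-loop trial: the fly's turning steers the grating orientation."""

    grating: GratingSpec = field(default_factory=lambda: GratingSpec(90.0, 0.0))
    duration_ms: float = 3000.0  # 30000 for technical-verification runs
    coupling_gain: float = -1.0

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")


StimulusSpec = Union[GratingSpec, BarSweepSpec, ClosedLoopSpec]


@dataclass(frozen=True)
class TrialSpec:
    """One trial: pre epoch (stationary), motion epoch, post epoch."""

    stimulus: StimulusSpec
    condition_id: str
    pre_ms: float = 500.0
    motion_ms: float = 3000.0
    post_ms: float = 500.0

    def __post_init__(self) -> None:
        if min(self.pre_ms, self.motion_ms, self.post_ms) < 0:
            raise ValueError("epoch durations must be >= 0")
        if isinstance(self.stimulus, BarSweepSpec):
            want = sweep_duration(self.stimulus) * 1000.0
            if abs(self.motion_ms - want) > 1e-9 * max(1.0, want):
                raise ValueError(
                    f"bar trial motion_ms must equal sweep_span/|omega| "
                    f"({want:.6g} ms), got {self.motion_ms}")

    @classmethod
    def for_grating(cls, spec: GratingSpec, condition_id: str, *,
                    pre_ms: float = 500.0, motion_ms: float = 3000.0,
                    post_ms: float = 500.0) -> "TrialSpec":
        return cls(spec, condition_id, pre_ms, motion_ms, post_ms)

    @classmethod
    def for_bar(cls, spec: BarSweepSpec, condition_id: str, *,
                pre_ms: float = 500.0, post_ms: float = 500.0) -> "TrialSpec":
        return cls(spec, condition_id, pre_ms, sweep_duration(spec) * 1000.0, post_ms)

    @classmethod
    def for_closed_loop(cls, spec: ClosedLoopSpec, condition_id: str = "closed-loop", *,
                        pre_ms: float = 500.0, post_ms: float = 500.0) -> "TrialSpec":
        return cls(spec, condition_id, pre_ms, spec.duration_ms, post_ms)

    @property
    def duration_ms(self) -> float:
        return self.pre_ms + self.motion_ms + self.post_ms

    @property
    def is_closed_loop(self) -> bool:
        return isinstance(self.stimulus, ClosedLoopSpec)

    def motion_time_s(self, t_s):
        """Clip trial time to the motion epoch; frozen during pre/post."""
        t = np.asarray(t_s, dtype=float)
        return np.clip(t - self.pre_ms / 1000.0, 0.0, self.motion_ms / 1000.0)


def temporal_frequency(g: GratingSpec) -> float:
    """Temporal frequency |ω|/λ in Hz of a moving grating."""
    if g.spatial_period_deg <= 0:
        raise ValueError("spatial_period_deg must be > 0")
    return abs(g.angular_velocity_dps) / g.spatial_period_deg


def sweep_duration(spec: BarSweepSpec) -> float:
    """Duration (s) of one full bar traversal: sweep_span / |ω|."""
    if spec.angular_velocity_dps == 0:
        raise ValueError("bar sweep requires angular_velocity_dps != 0")
    return spec.sweep_span_deg / abs(spec.angular_velocity_dps)


def _grating_luminance(g: GratingSpec, azimuth_deg, t_motion_s):
    lam = g.spatial_period_deg
    phase = np.mod(np.asarray(azimuth_deg, dtype=float)
                   - g.angular_velocity_dps * np.asarray(t_motion_s, dtype=float)
                   - g.phase0_deg, lam)
    bright = np.floor(phase / (lam / 2.0)) == 0
    return np.where(bright, g.bright_luminance, g.dark_luminance)


def _bar_luminance(b: BarSweepSpec, azimuth_deg, t_motion_s):
    center = b.center_deg(t_motion_s)
    inside = np.abs(np.asarray(azimuth_deg, dtype=float) - center) < b.bar_width_deg / 2.0
    return np.where(inside, b.bar_luminance, b.background_luminance)


def luminance_at(trial_or_spec, azimuth_deg, t_s=0.0):
    """Luminance in [0, 1] at a given azimuth and time.

    When given a :class:`TrialSpec`, ``t_s`` is time since trial start: the
    pattern position is frozen at its initial/final value during the pre/post
    epochs, and bar trials show the uniform background (a dark screen) outside
    the motion epoch.  When given a bare stimulus spec, ``t_s`` is motion time.
    Scalar in, scalar out; arrays broadcast.
    """
    scalar = np.isscalar(azimuth_deg) and np.isscalar(t_s)
    if isinstance(trial_or_spec, TrialSpec):
        trial = trial_or_spec
        spec = trial.stimulus
        tm = trial.motion_time_s(t_s)
        if isinstance(spec, BarSweepSpec):
            t = np.asarray(t_s, dtype=float)
            in_motion = (t >= trial.pre_ms / 1000.0) & (
                t < (trial.pre_ms + trial.motion_ms) / 1000.0)
            lum = np.where(in_motion, _bar_luminance(spec, azimuth_deg, tm),
                           spec.background_luminance)
        elif isinstance(spec, ClosedLoopSpec):
            lum = _grating_luminance(spec.grating, azimuth_deg, tm)
        else:
            lum = _grating_luminance(spec, azimuth_deg, tm)
    else:
        spec = trial_or_spec
        if isinstance(spec, BarSweepSpec):
            lum = _bar_luminance(spec, azimuth_deg, t_s)
        elif isinstance(spec, ClosedLoopSpec):
            lum = _grating_luminance(spec.grating, azimuth_deg, t_s)
        else:
            lum = _grating_luminance(spec, azimuth_deg, t_s)
    return float(lum) if scalar else lum


@dataclass(frozen=True)
class Protocol:
    """A set of conditions presented as randomly ordered repeated blocks."""

    kind: str
    conditions: tuple[TrialSpec, ...]
    n_blocks: int = 6
    startup_delay_ms: float = 10000.0
    rng_seed: int = 0
    closed_loop: TrialSpec | None = None  # interleaved once per block when set

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not self.conditions:
            raise ValueError("protocol needs at least one condition")
        ids = [c.condition_id for c in self.conditions]
        if len(set(ids)) != len(ids):
            raise ValueError("condition_id values must be unique")


def _direction_suffix(omega: float) -> str:
    return "cw" if omega > 0 else "ccw"


def build_protocol(kind: str, *, n_blocks: int = 6, startup_delay_ms: float = 10000.0,
                   rng_seed: int = 0, include_closed_loop: bool = True,
                   closed_loop_duration_ms: float = 3000.0,
                   sweep_span_deg: float = DEFAULT_SWEEP_SPAN_DEG) -> Protocol:
    """Build one of the three standard protocols: temporal, spatial, or bar."""
    conditions: list[TrialSpec] = []
    if kind == "temporal":
        for speed in TEMPORAL_SPEEDS_DPS:
            for sign in (+1.0, -1.0):
                g = GratingSpec(90.0, sign * speed)
                tf = temporal_frequency(g)
                cid = f"grating-tf{tf:g}-{_direction_suffix(sign)}"
                conditions.append(TrialSpec.for_grating(g, cid))
    elif kind == "spatial":
        for lam in SPATIAL_PERIODS_DEG:
            for sign in (+1.0, -1.0):
                g = GratingSpec(lam, sign * 7.5 * lam)  # TF fixed at 7.5 Hz
                cid = f"grating-sp{lam:g}-{_direction_suffix(sign)}"
                conditions.append(TrialSpec.for_grating(g, cid))
    elif kind == "bar":
        for speed in BAR_SPEEDS_DPS:
            for sign in (+1.0, -1.0):
                b = BarSweepSpec(angular_velocity_dps=sign * speed,
                                 sweep_span_deg=sweep_span_deg)
                cid = f"bar-w{speed:g}-{_direction_suffix(sign)}"
                conditions.append(TrialSpec.for_bar(b, cid))
    else:
        raise ValueError(f"unknown protocol kind {kind!r}; "
                         "expected 'temporal', 'spatial' or 'bar'")
    cl = None
    if include_closed_loop:
        cl = TrialSpec.for_closed_loop(ClosedLoopSpec(duration_ms=closed_loop_duration_ms))
    return Protocol(kind=kind, conditions=tuple(conditions), n_blocks=n_blocks,
                    startup_delay_ms=startup_delay_ms, rng_seed=rng_seed,
                    closed_loop=cl)


def randomize_blocks(protocol: Protocol, seed: int | None = None) -> list[TrialSpec]:
    """Concatenate ``n_blocks`` independent uniform permutations of the conditions.

    When the protocol defines a closed-loop trial it is appended after each
    block.  Deterministic for a fixed seed (default: the protocol's own seed).
    """
    if not protocol.conditions:
        raise ValueError("protocol has no conditions")
    rng = np.random.default_rng(protocol.rng_seed if seed is None else seed)
    out: list[TrialSpec] = []
    conds = list(protocol.conditions)
    for _ in range(protocol.n_blocks):
        order = rng.permutation(len(conds))
        out.extend(conds[i] for i in order)
        if protocol.closed_loop is not None:
            out.append(protocol.closed_loop)
    return out


# --- condition metadata used by the engine log and the analysis -----------------

def condition_info(trial: TrialSpec) -> dict:
    """Kind, tuning parameter and direction of a trial's condition.

    The tuning parameter is what a tuning curve is plotted against: temporal
    frequency (Hz) for gratings of the temporal protocol, spatial period (deg)
    for the spatial protocol, |ω| (deg/s) for bar sweeps.  Both grating values
    are reported; the protocol kind picks the axis.
    """
    s = trial.stimulus
    if isinstance(s, ClosedLoopSpec):
        return {"kind": "closed-loop", "param": 0.0, "direction": "cw", "omega": 0.0}
    if isinstance(s, BarSweepSpec):
        return {"kind": "bar", "param": abs(s.angular_velocity_dps),
                "direction": _direction_suffix(s.angular_velocity_dps),
                "omega": s.angular_velocity_dps}
    # grating: choose the axis from the condition id written by build_protocol
    if trial.condition_id.startswith("grating-sp"):
        param = s.spatial_period_deg
    else:
        param = temporal_frequency(s)
    return {"kind": "grating", "param": param,
            "direction": _direction_suffix(s.angular_velocity_dps),
            "omega": s.angular_velocity_dps}


# --- serialization --------------------------------------------------------------

def protocol_to_yaml(protocol: Protocol) -> str:
    """Serialize a standard protocol to a YAML document."""
    doc = {
        "kind": protocol.kind,
        "n_blocks": protocol.n_blocks,
        "startup_delay_ms": protocol.startup_delay_ms,
        "rng_seed": protocol.rng_seed,
        "include_closed_loop": protocol.closed_loop is not None,
    }
    if protocol.closed_loop is not None:
        doc["closed_loop_duration_ms"] = protocol.closed_loop.motion_ms
    return yaml.safe_dump(doc, sort_keys=True)


def protocol_from_yaml(text: str) -> Protocol:
    doc = yaml.safe_load(text)
    return build_protocol(
        doc["kind"],
        n_blocks=int(doc.get("n_blocks", 6)),
        startup_delay_ms=float(doc.get("startup_delay_ms", 10000.0)),
        rng_seed=int(doc.get("rng_seed", 0)),
        include_closed_loop=bool(doc.get("include_closed_loop", True)),
        closed_loop_duration_ms=float(doc.get("closed_loop_duration_ms", 3000.0)),
    )


def trials_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    """Tidy table of an ordered trial list (one row per trial)."""
    rows = []
    t_ms = 0.0
    for i, tr in enumerate(trials):
        info = condition_info(tr)
        rows.append({
            "trial_index": i,
            "condition_id": tr.condition_id,
            "kind": info["kind"],
            "param": info["param"],
            "omega_dps": info["omega"],
            "direction": info["direction"],
            "pre_ms": tr.pre_ms,
            "motion_ms": tr.motion_ms,
            "post_ms": tr.post_ms,
            "t_start_planned_ms": t_ms,
        })
        t_ms += tr.duration_ms
    return pd.DataFrame(rows)
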