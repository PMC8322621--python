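"""Event-based trial execution with a simulated clock and injectable transport.

The experiment server and the display client exchange parameter updates over a
network.  The two sides are deliberately decoupled: the server announces scene
parameters (condition, angular velocity, orientation) at epoch boundaries, and
the client renders a frame every display refresh using the *latest delivered*
parameters — if an update has not arrived by the frame deadline the previous
content is shown again.  Every state change is logged as a time-stamped
key–value entry, and the client records per-frame rendering status, so frame
drops and network latency can be accounted for post hoc.

Everything here runs on one simulated clock (integer-microsecond resolution,
exported in ms) with an injectable :class:`TransportModel`; a real network or
browser is never required.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .geometry import DisplayGeometry
from .stimuli import TrialSpec, ClosedLoopSpec, condition_info

__all__ = [
    "TransportModel",
    "RenderTimeoutModel",
    "FrameRecord",
    "EventLogEntry",
    "EventLog",
    "ScheduledTrial",
    "ExperimentResult",
    "schedule_trials",
    "run_experiment",
    "frame_statistics",
    "roundtrip_latency_trial",
    "RoundTripResult",
    "closed_loop_update",
    "frame_records_to_csv",
    "frame_records_from_csv",
]

_US = 1000  # microseconds per millisecond; timestamps are integer us internally


def _quantize_ms(t_ms: float) -> float:
    """Round a time to the integer-microsecond grid, returned in ms."""
    return round(t_ms * _US) / _US


@dataclass(frozen=True)
class TransportModel:
    """One-way message latency: fixed floor plus optional exponential jitter.

    Deliveries are in-order: a message never overtakes an earlier one.
    """

    mean_latency_ms: float = 0.0
    jitter_ms: float = 0.0  # mean of the exponential jitter component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_latency_ms < 0 or self.jitter_ms < 0:
            raise ValueError("latencies must be >= 0")

    def one_way(self, n: int, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw n one-way latencies (ms)."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        lat = np.full(n, float(self.mean_latency_ms))
        if self.jitter_ms > 0:
            lat = lat + rng.exponential(self.jitter_ms, size=n)
        return lat


@dataclass(frozen=True)
class RenderTimeoutModel:
    """Injectable render delays: every nth frame and/or a Bernoulli fraction.

    A delayed frame completes ``delay_frames`` refresh intervals late and shows
    the content that was current one deadline earlier (the render-timeout rule).
    """

    every_n: int | None = None
    delay_frames: int = 1
    probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.every_n is not None and self.every_n < 1:
            raise ValueError("every_n must be >= 1")
        if self.delay_frames < 1:
            raise ValueError("delay_frames must be >= 1")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")

    def delays(self, n_frames: int) -> np.ndarray:
        """Per-frame delay in whole refresh intervals (0 = on time)."""
        d = np.zeros(n_frames, dtype=int)
        if self.every_n is not None:
            d[self.every_n - 1::self.every_n] = self.delay_frames
        if self.probability > 0:
            rng = np.random.default_rng(self.seed)
            d[rng.random(n_frames) < self.probability] = self.delay_frames
        return d


@dataclass(frozen=True)
class FrameRecord:
    """Rendering status of one display frame."""

    frame_index: int
    scheduled_ms: float
    rendered_ms: float
    params_version_shown: int
    on_time: bool

    def __post_init__(self) -> None:
        if self.rendered_ms < self.scheduled_ms:
            raise ValueError("rendered_ms must be >= scheduled_ms")


@dataclass(frozen=True)
class EventLogEntry:
    t_ms: float
    source: str  # "server" or "client"
    key: str
    value: object  # str | int | float


class EventLog:
    """Time-stamped key–value long-format log from both server and client."""

    def __init__(self, entries: Sequence[EventLogEntry] = ()):
        self.entries: list[EventLogEntry] = list(entries)

    def append(self, t_ms: float, source: str, key: str, value) -> None:
        self.entries.append(EventLogEntry(_quantize_ms(t_ms), source, key, value))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventLog) and self.entries == other.entries

    def to_csv(self, path_or_buf) -> None:
        """Write as long-format CSV: t_ms, source, key, value."""
        own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
        f = open(path_or_buf, "w", newline="") if own else path_or_buf
        try:
            w = csv.writer(f)
            w.writerow(["t_ms", "source", "key", "value"])
            for e in self.entries:
                w.writerow([repr(e.t_ms), e.source, e.key,
                            repr(e.value) if isinstance(e.value, float) else e.value])
        finally:
            if own:
                f.close()

    @classmethod
    def from_csv(cls, path_or_buf) -> "EventLog":
        own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
        f = open(path_or_buf, "r", newline="") if own else path_or_buf
        try:
            r = csv.reader(f)
            header = next(r)
            if header[:4] != ["t_ms", "source", "key", "value"]:
                raise ValueError(f"unexpected event-log header: {header}")
            log = cls()
            for row in r:
                t, source, key, raw = row
                log.entries.append(EventLogEntry(float(t), source, key, _parse_value(raw)))
            return log
        finally:
            if own:
                f.close()


def _parse_value(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


@dataclass(frozen=True)
class ScheduledTrial:
    """A trial placed on the experiment time axis."""

    index: int
    trial: TrialSpec
    t_start_ms: float
    t_motion_on_ms: float
    t_motion_off_ms: float
    t_end_ms: float

    @property
    def is_closed_loop(self) -> bool:
        return self.trial.is_closed_loop


def schedule_trials(trials: Sequence[TrialSpec],
                    startup_delay_ms: float = 10000.0) -> list[ScheduledTrial]:
    """Lay trials back-to-back after the startup delay."""
    out = []
    t = float(startup_delay_ms)
    for i, tr in enumerate(trials):
        out.append(ScheduledTrial(
            index=i, trial=tr, t_start_ms=t,
            t_motion_on_ms=t + tr.pre_ms,
            t_motion_off_ms=t + tr.pre_ms + tr.motion_ms,
            t_end_ms=t + tr.duration_ms))
        t += tr.duration_ms
    return out


class ExperimentResult(NamedTuple):
    event_log: EventLog
    frame_records: list[FrameRecord]
    fictrac: "object | None"  # FicTracData when a fly model was supplied
    schedule: list[ScheduledTrial]


def run_experiment(trials: Sequence[TrialSpec], geom: DisplayGeometry,
                   transport: TransportModel, fly=None, *,
                   startup_delay_ms: float = 10000.0,
                   render_timeout: RenderTimeoutModel | None = None
                   ) -> ExperimentResult:
    """Execute a trial list on the simulated clock.

    The clock advances in display-frame steps (1/refresh_rate).  The server
    emits parameter updates at trial/epoch boundaries; each update travels
    through ``transport`` and the client applies the latest delivered update at
    every frame deadline.  Frames delayed by ``render_timeout`` re-show the
    previous content and are logged as late.  When a
    :class:`~flytread.simfly.FlyModel` is supplied, its walking is simulated at
    the camera rate, emitted as FicTrac-format frames, and (for closed-loop
    trials) fed back into the logged stimulus orientation.

    Deterministic: identical trials, geometry, transport and fly (seeds
    included) produce bit-identical logs.
    """
    if not trials:
        raise ValueError("trials must be non-empty")
    schedule = schedule_trials(trials, startup_delay_ms)
    total_ms = schedule[-1].t_end_ms
    dt_ms = geom.frame_interval_ms
    n_frames = math.ceil(total_ms * geom.refresh_rate_hz / 1000.0)

    log = EventLog()
    log.append(0.0, "server", "experiment-start", len(trials))

    # server-side parameter updates (sent through the transport)
    send_times: list[float] = [0.0]  # version 1: initial blank scene
    for st in schedule:
        info = condition_info(st.trial)
        log.append(st.t_start_ms, "server", "trial-start", st.index)
        log.append(st.t_start_ms, "server", "condition", st.trial.condition_id)
        log.append(st.t_start_ms, "server", "kind", info["kind"])
        log.append(st.t_start_ms, "server", "param", float(info["param"]))
        log.append(st.t_start_ms, "server", "direction", info["direction"])
        log.append(st.t_motion_on_ms, "server", "motion-on", st.index)
        log.append(st.t_motion_on_ms, "server", "omega", float(info["omega"]))
        log.append(st.t_motion_off_ms, "server", "motion-off", st.index)
        log.append(st.t_end_ms, "server", "trial-end", st.index)
        send_times.extend([st.t_start_ms, st.t_motion_on_ms, st.t_motion_off_ms])
    log.append(total_ms, "server", "experiment-end", len(trials))

    sends = np.asarray(send_times)
    rng = np.random.default_rng(transport.seed)
    arrivals = sends + transport.one_way(len(sends), rng)
    arrivals = np.maximum.accumulate(arrivals)  # in-order delivery
    arrivals = np.round(arrivals * _US) / _US
    for v, t_arr in enumerate(arrivals, start=1):
        log.append(t_arr, "client", "params-applied", v)

    # per-frame rendering with the render-timeout rule
    scheduled = np.round(np.arange(n_frames) * dt_ms * _US) / _US
    delays = (render_timeout.delays(n_frames) if render_timeout is not None
              else np.zeros(n_frames, dtype=int))
    rendered = np.round((scheduled + delays * dt_ms) * _US) / _US
    # a delayed frame shows the content that was current `delay` deadlines earlier
    content_time = scheduled - delays * dt_ms
    versions = np.searchsorted(arrivals, content_time, side="right")
    records = [
        FrameRecord(i, float(scheduled[i]), float(rendered[i]), int(versions[i]),
                    bool(delays[i] == 0))
        for i in range(n_frames)
    ]

    fictrac = None
    if fly is not None:
        from .simfly import simulate_fly  # local import; simfly renders stimuli
        fictrac = simulate_fly(fly, schedule, geom)
        _log_closed_loop(log, schedule, fictrac, geom, transport, rng)
    log.entries.sort(key=lambda e: (e.t_ms, e.source != "server"))
    return ExperimentResult(log, records, fictrac, schedule)


def _log_closed_loop(log: EventLog, schedule, fictrac, geom, transport,
                     rng: np.random.Generator) -> None:
    """Apply fly turning to closed-loop trial orientation and log it per frame.

    orientation' = orientation + gain * delta_heading, applied on the next
    delivered update — i.e. one transport delivery after the turn happened.
    """
    from .fictrac import DEFAULT_FORMAT
    heading = np.unwrap(fictrac.heading_rad)
    t_cam_ms = np.concatenate([[0.0], np.cumsum(fictrac.delta_timestamp_s)]) * 1000.0
    heading = np.concatenate([[heading[0]], heading])
    dt_ms = geom.frame_interval_ms
    for st in schedule:
        if not st.is_closed_loop:
            continue
        spec: ClosedLoopSpec = st.trial.stimulus
        n = int(np.floor((st.t_motion_off_ms - st.t_motion_on_ms) / dt_ms))
        frame_t = st.t_motion_on_ms + np.arange(n + 1) * dt_ms
        lat = transport.one_way(n + 1, rng)
        h = np.interp(frame_t, t_cam_ms, heading)
        delta = np.rad2deg(np.diff(h, prepend=h[0]))
        base = spec.grating.angular_velocity_dps * (frame_t - st.t_motion_on_ms) / 1000.0
        orientation = base + spec.coupling_gain * np.cumsum(delta)
        for t, l, o in zip(frame_t, lat, orientation):
            log.append(t + l, "server", "orientation", float(o))


def frame_statistics(records: Sequence[FrameRecord],
                     frame_interval_ms: float | None = None
                     ) -> tuple[float, dict[int, int]]:
    """On-time fraction and a histogram of delayed frames by whole intervals.

    Histogram keys are 1, 2 and 3, where 3 collects delays of >= 3 intervals;
    zero-count bins are omitted.
    """
    if not records:
        raise ValueError("frame record list is empty")
    if frame_interval_ms is None:
        if len(records) < 2:
            raise ValueError("cannot infer frame interval from one record")
        frame_interval_ms = float(np.median(np.diff([r.scheduled_ms for r in records])))
    n_on = sum(r.on_time for r in records)
    hist: dict[int, int] = {}
    for r in records:
        if r.on_time:
            continue
        k = int(round((r.rendered_ms - r.scheduled_ms) / frame_interval_ms))
        k = min(max(k, 1), 3)
        hist[k] = hist.get(k, 0) + 1
    return n_on / len(records), hist


class RoundTripResult(NamedTuple):
    latencies_ms: np.ndarray
    fraction_within: dict[int, float]  # k -> fraction within k frame intervals


def roundtrip_latency_trial(transport: TransportModel, n: int, seed: int | None = None,
                            refresh_rate_hz: float = 60.0) -> RoundTripResult:
    """Simulate n server->client->server round-trips.

    Reports the fraction of round-trips completing within k inter-frame
    intervals (k = 1..4) of a display refreshing at ``refresh_rate_hz``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(transport.seed if seed is None else seed)
    rtt = transport.one_way(n, rng) + transport.one_way(n, rng)
    interval = 1000.0 / refresh_rate_hz
    fractions = {k: float(np.mean(rtt <= k * interval)) for k in range(1, 5)}
    return RoundTripResult(rtt, fractions)


def closed_loop_update(camera_orientation_deg: float, fly_delta_heading_deg: float,
                       gain: float) -> float:
    """New stimulus orientation after one closed-loop step.

    With gain -1 a fly turn of +10 deg moves the stimulus by -10 deg, i.e. the
    pattern is stabilized on the retina.
    """
    return camera_orientation_deg + gain * fly_delta_heading_deg


def frame_records_to_csv(records: Sequence[FrameRecord], path_or_buf) -> None:
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    f = open(path_or_buf, "w", newline="") if own else path_or_buf
    try:
        w = csv.writer(f)
        w.writerow(["frame_index", "scheduled_ms", "rendered_ms",
                    "params_version_shown", "on_time"])
        for r in records:
            w.writerow([r.frame_index, repr(r.scheduled_ms), repr(r.rendered_ms),
                        r.params_version_shown, int(r.on_time)])
    finally:
        if own:
            f.close()


def frame_records_from_csv(path_or_buf) -> list[FrameRecord]:
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    f = open(path_or_buf, "r", newline="") if own else path_or_buf
    try:
        r = csv.reader(f)
        next(r)  # header
        return [FrameRecord(int(a), float(b), float(c), int(d), bool(int(e)))
                for a, b, c, d, e in r]
    finally:
        if own:
            f.close()
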