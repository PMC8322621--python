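"""Turning-response analysis: from event logs + treadmill data to tuning curves.

The chain mirrors how tethered-fly optomotor data are conventionally reduced:

1. convert the wrapped heading of each FicTrac recording to yaw velocity
   (deg/s) and smooth with a centered sliding window of 5 camera frames;
2. annotate every camera frame with the active trial, condition and epoch
   (pre / motion / post) from the time-stamped event log — the two streams run
   at different rates (display vs camera), so alignment is by timestamp;
3. average within each fly: per-trial means over the motion epoch, then the
   mean across that fly's trials of a condition;
4. combine directions: counterclockwise responses are scaled by -1 and
   averaged with the clockwise responses, cancelling any direction-independent
   turning bias;
5. average across flies (each fly weighted equally regardless of trial count)
   and report mean +- SEM (sd / sqrt(n_flies)) per condition.

Closed-loop trials present in the logs are excluded from every tuning
computation.  The stimulus epoch is half-open, [motion onset, motion offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import EventLog, ExperimentResult
from .fictrac import FicTracData, SphereSpec, translational_speed, yaw_velocity
from .stimuli import DEFAULT_SWEEP_SPAN_DEG

__all__ = [
    "TrialTimeSeries",
    "TuningCurve",
    "AnalysisResult",
    "BarProfile",
    "trial_table",
    "merge_logs",
    "smooth_sliding",
    "extract_trials",
    "per_fly_then_population",
    "combine_directions",
    "condition_means",
    "tuning_curve",
    "analyze_tuning",
    "bar_profile",
    "plot_tuning_curve",
]


@dataclass(frozen=True)
class TrialTimeSeries:
    """Smoothed yaw-velocity trace of one trial, time-locked to motion onset."""

    fly_id: int
    trial_index: int
    condition_id: str
    kind: str
    param: float
    direction: str  # "cw" | "ccw"
    t: np.ndarray   # s relative to motion onset (negative during pre epoch)
    yaw_dps: np.ndarray
    motion_s: float
    pre_s: float


@dataclass(frozen=True)
class TuningCurve:
    """Per-condition mean +- SEM turning velocity across flies."""

    x: np.ndarray
    mean_dps: np.ndarray
    sem_dps: np.ndarray
    n_flies: int
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "mean_dps": self.mean_dps,
                             "sem_dps": self.sem_dps, "n_flies": self.n_flies})


def trial_table(event_log: EventLog) -> pd.DataFrame:
    """Tabulate trials from the server side of an event log."""
    trials: dict[int, dict] = {}

    def rec(idx):
        return trials.setdefault(int(idx), {"trial_index": int(idx)})

    for e in event_log:
        if e.source != "server":
            continue
        if e.key == "trial-start":
            rec(e.value)["t_start_s"] = e.t_ms / 1000.0
            current = rec(e.value)
        elif e.key in ("condition", "kind", "direction", "param"):
            current[{"condition": "condition_id"}.get(e.key, e.key)] = e.value
        elif e.key == "motion-on":
            rec(e.value)["t_motion_on_s"] = e.t_ms / 1000.0
        elif e.key == "motion-off":
            rec(e.value)["t_motion_off_s"] = e.t_ms / 1000.0
        elif e.key == "trial-end":
            rec(e.value)["t_end_s"] = e.t_ms / 1000.0
    df = pd.DataFrame(sorted(trials.values(), key=lambda r: r["trial_index"]))
    if len(df):
        df["closed_loop"] = df["kind"] == "closed-loop"
    return df


def merge_logs(event_log: EventLog, fictrac: FicTracData) -> pd.DataFrame:
    """Annotate every camera frame with trial, condition and epoch.

    Returns a tidy table keyed by time with one row per yaw-velocity sample
    (camera frames 2..n).  Frames outside any trial get trial_index -1 and
    epoch "none".  Raises if the two streams do not overlap in time.
    """
    trials = trial_table(event_log)
    if trials.empty:
        raise ValueError("event log contains no trials")
    t = fictrac.frame_times_s[1:]
    yaw = yaw_velocity(fictrac)
    if t[-1] < trials["t_start_s"].iloc[0] or t[0] >= trials["t_end_s"].iloc[-1]:
        raise ValueError("treadmill data and event log do not overlap in time")

    starts = trials["t_start_s"].to_numpy()
    idx = np.searchsorted(starts, t, side="right") - 1
    idx_c = np.clip(idx, 0, len(trials) - 1)
    inside = (idx >= 0) & (t < trials["t_end_s"].to_numpy()[idx_c])
    on = trials["t_motion_on_s"].to_numpy()[idx_c]
    off = trials["t_motion_off_s"].to_numpy()[idx_c]
    epoch = np.where(~inside, "none",
                     np.where(t < on, "pre", np.where(t < off, "motion", "post")))

    def col(name, default):
        vals = trials[name].to_numpy()[idx_c]
        return np.where(inside, vals, default)

    return pd.DataFrame({
        "t_s": t,
        "yaw_dps": yaw,
        "speed_mm_s": translational_speed(fictrac)[1:],
        "trial_index": np.where(inside, idx_c, -1),
        "condition_id": col("condition_id", ""),
        "kind": col("kind", ""),
        "param": np.where(inside, trials["param"].to_numpy(dtype=float)[idx_c], np.nan),
        "direction": col("direction", ""),
        "epoch": epoch,
        "closed_loop": np.where(inside, trials["closed_loop"].to_numpy()[idx_c], False),
    })


def smooth_sliding(series, window: int = 5) -> np.ndarray:
    """Centered moving average over ``window`` samples (odd).

    At the edges the window truncates symmetrically, so the output has the same
    length as the input and a constant series is unchanged.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    x = np.asarray(series, dtype=float)
    if window == 1 or len(x) == 0:
        return x.copy()
    kernel = np.ones(window)
    return np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones(len(x)), kernel, mode="same")


def extract_trials(merged: pd.DataFrame, fly_id: int = 0, window: int = 5,
                   include_closed_loop: bool = False) -> list[TrialTimeSeries]:
    """Slice a merged table into per-trial time series.

    Smoothing (sliding window of ``window`` camera frames) is applied to the
    fly's continuous yaw series *before* slicing and averaging.  Closed-loop
    trials are dropped unless requested.
    """
    merged = merged.sort_values("t_s")
    yaw_smooth = smooth_sliding(merged["yaw_dps"].to_numpy(), window)
    out: list[TrialTimeSeries] = []
    t_all = merged["t_s"].to_numpy()
    trial_idx = merged["trial_index"].to_numpy()
    for ti in np.unique(trial_idx):
        if ti < 0:
            continue
        sel = trial_idx == ti
        rows = merged.loc[sel]
        if bool(rows["closed_loop"].iloc[0]) and not include_closed_loop:
            continue
        epochs = rows["epoch"].to_numpy()
        motion = epochs == "motion"
        if not motion.any():
            continue
        t_on = t_all[sel][motion][0]
        t_rel = t_all[sel] - t_on
        pre_s = float(t_rel[0] * -1) if t_rel[0] < 0 else 0.0
        motion_s = float(np.count_nonzero(motion)) * float(np.median(np.diff(t_all[sel])))
        out.append(TrialTimeSeries(
            fly_id=fly_id, trial_index=int(ti),
            condition_id=str(rows["condition_id"].iloc[0]),
            kind=str(rows["kind"].iloc[0]), param=float(rows["param"].iloc[0]),
            direction=str(rows["direction"].iloc[0]),
            t=t_rel, yaw_dps=yaw_smooth[sel.to_numpy() if hasattr(sel, "to_numpy") else sel],
            motion_s=motion_s, pre_s=pre_s))
    return out


def per_fly_then_population(trials: Sequence[TrialTimeSeries],
                            dt_s: float | None = None) -> pd.DataFrame:
    """Two-stage trace averaging on a common time grid.

    Stage 1 averages each fly's trials per condition; stage 2 averages the
    per-fly means with equal weight per fly.  Returns a tidy frame with columns
    condition_id, t_s (relative to motion onset), mean_dps, n_flies.
    """
    if not trials:
        raise ValueError("no trials to average")
    if dt_s is None:
        dt_s = float(np.median(np.diff(trials[0].t)))
    frames = []
    for tr in trials:
        b = np.round(tr.t / dt_s).astype(int)
        frames.append(pd.DataFrame({"condition_id": tr.condition_id,
                                    "fly_id": tr.fly_id, "bin": b,
                                    "yaw_dps": tr.yaw_dps}))
    df = pd.concat(frames, ignore_index=True)
    per_fly = (df.groupby(["condition_id", "fly_id", "bin"], sort=True)["yaw_dps"]
               .mean().reset_index())
    pop = (per_fly.groupby(["condition_id", "bin"], sort=True)["yaw_dps"]
           .agg(["mean", "count"]).reset_index())
    pop["t_s"] = pop["bin"] * dt_s
    return pop.rename(columns={"mean": "mean_dps", "count": "n_flies"})[
        ["condition_id", "t_s", "mean_dps", "n_flies"]]


def combine_directions(cw, ccw):
    """(cw + (-1) * ccw) / 2 on a common grid.

    Scaling the counterclockwise response by -1 before averaging folds both
    directions onto one axis and cancels direction-independent turning bias.
    """
    cw = np.asarray(cw, dtype=float)
    ccw = np.asarray(ccw, dtype=float)
    if cw.shape != ccw.shape:
        raise ValueError(f"direction traces differ in shape: {cw.shape} vs {ccw.shape}")
    out = (cw - ccw) / 2.0
    return float(out) if out.ndim == 0 else out


def condition_means(trials: Sequence[TrialTimeSeries]) -> pd.DataFrame:
    """Per-fly mean turning during the motion epoch, per condition x direction.

    Stage 1 of the averaging: mean over [motion onset, offset) per trial, then
    mean over the fly's trials of each condition.
    """
    rows = []
    for tr in trials:
        in_motion = (tr.t >= 0) & (tr.t < tr.motion_s)
        rows.append({"fly_id": tr.fly_id, "kind": tr.kind, "param": tr.param,
                     "direction": tr.direction,
                     "value": float(tr.yaw_dps[in_motion].mean())})
    df = pd.DataFrame(rows)
    return (df.groupby(["fly_id", "kind", "param", "direction"], sort=True)["value"]
            .mean().reset_index())


def tuning_curve(per_fly_combined: pd.DataFrame, label: str = "") -> TuningCurve:
    """Across-fly mean +- SEM of per-fly combined responses.

    Input columns: fly_id, param, value (one combined value per fly and
    condition).  SEM = sd / sqrt(n_flies); NaN (flagged undefined) when fewer
    than two flies contribute.
    """
    g = per_fly_combined.groupby("param", sort=True)["value"]
    mean = g.mean()
    n = g.count()
    sd = g.std(ddof=1)
    sem = np.where(n.to_numpy() >= 2, sd.to_numpy() / np.sqrt(n.to_numpy()), np.nan)
    return TuningCurve(x=mean.index.to_numpy(dtype=float),
                       mean_dps=mean.to_numpy(), sem_dps=sem,
                       n_flies=int(n.max()), label=label)


@dataclass(frozen=True)
class AnalysisResult:
    tuning: TuningCurve
    per_fly: pd.DataFrame           # fly_id, param, value (combined)
    traces: pd.DataFrame            # population traces per condition
    n_closed_loop_excluded: int
    mean_forward_speed_mm_s: float


def _per_fly_combined(trials: Sequence[TrialTimeSeries]) -> pd.DataFrame:
    means = condition_means(trials)
    wide = means.pivot_table(index=["fly_id", "kind", "param"], columns="direction",
                             values="value").reset_index()
    for d in ("cw", "ccw"):
        if d not in wide:
            wide[d] = np.nan
    wide["value"] = combine_directions(wide["cw"].to_numpy(), wide["ccw"].to_numpy())
    return wide[["fly_id", "kind", "param", "value"]]


def analyze_tuning(runs: Sequence, window: int = 5, label: str = "",
                   compute_traces: bool = True) -> AnalysisResult:
    """Full per-fly-then-population analysis of a set of experiment runs.

    ``runs`` is a sequence of per-fly inputs: either
    :class:`~flytread.engine.ExperimentResult` or ``(event_log, fictrac)``
    pairs.  Closed-loop trials are excluded (their count is reported).
    """
    all_trials: list[TrialTimeSeries] = []
    n_cl = 0
    speeds = []
    for fly_id, run in enumerate(runs):
        log, fictrac = (run.event_log, run.fictrac) if isinstance(
            run, ExperimentResult) else (run[0], run[1])
        merged = merge_logs(log, fictrac)
        tt = trial_table(log)
        n_cl += int(tt["closed_loop"].sum())
        speeds.append(float(merged.loc[merged["epoch"] != "none", "speed_mm_s"].mean()))
        all_trials.extend(extract_trials(merged, fly_id=fly_id, window=window))
    per_fly = _per_fly_combined(all_trials)
    curve = tuning_curve(per_fly, label=label)
    traces = (per_fly_then_population(all_trials) if compute_traces
              else pd.DataFrame(columns=["condition_id", "t_s", "mean_dps", "n_flies"]))
    return AnalysisResult(tuning=curve, per_fly=per_fly, traces=traces,
                          n_closed_loop_excluded=n_cl,
                          mean_forward_speed_mm_s=float(np.mean(speeds)))


@dataclass(frozen=True)
class BarProfile:
    """Combined bar-following trace with the deterministic bar trajectory."""

    omega_dps: float
    t_s: np.ndarray
    mean_dps: np.ndarray
    bar_azimuth_deg: np.ndarray  # expected CW bar-center position, NaN outside sweep
    n_flies: int


def bar_profile(trials: Sequence[TrialTimeSeries],
                sweep_span_deg: float = DEFAULT_SWEEP_SPAN_DEG) -> list[BarProfile]:
    """Time-locked combined mean traces per bar speed, with bar positions.

    CCW trials are time-aligned and scaled by -1 (equivalently mirrored), so
    the overlaid trajectory is the clockwise bar's: it enters at
    -span/2, crosses the midline at t = (span/2)/omega, and exits at +span/2.
    """
    bar_trials = [t for t in trials if t.kind == "bar"]
    if not bar_trials:
        raise ValueError("no bar trials supplied")
    folded = []
    for tr in bar_trials:
        yaw = tr.yaw_dps if tr.direction == "cw" else -tr.yaw_dps
        folded.append(TrialTimeSeries(
            tr.fly_id, tr.trial_index, f"bar-{tr.param:g}", tr.kind, tr.param,
            "cw", tr.t, yaw, tr.motion_s, tr.pre_s))
    traces = per_fly_then_population(folded)
    out = []
    for cid, grp in traces.groupby("condition_id"):
        omega = float(grp["condition_id"].iloc[0].split("-")[1])
        t = grp["t_s"].to_numpy()
        pos = -sweep_span_deg / 2.0 + omega * t
        pos[(t < 0) | (pos > sweep_span_deg / 2.0)] = np.nan
        out.append(BarProfile(omega, t, grp["mean_dps"].to_numpy(), pos,
                              int(grp["n_flies"].max())))
    return sorted(out, key=lambda p: p.omega_dps)


def plot_tuning_curve(curve: TuningCurve, ax=None, logx: bool = True):
    """Mean +- SEM tuning curve in the conventional layout."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(curve.x, curve.mean_dps, yerr=curve.sem_dps, marker="o",
                capsize=3, lw=1.5)
    if logx:
        ax.set_xscale("log")
    ax.axhline(0.0, color="0.7", lw=0.8)
    ax.set_xlabel(curve.label or "condition parameter")
    ax.set_ylabel("turning velocity (deg/s)")
    return ax
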