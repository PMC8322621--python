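"""Experiment configuration: validation, serialization, reproducible runs.

An :class:`ExperimentConfig` wires together the display geometry, a protocol, a
transport model and (optionally) a population of synthetic flies.  ``run``
executes the full simulate -> log -> analyze pipeline and writes every artifact
plus a manifest; identical configs (seeds included) produce byte-identical data
outputs and therefore identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .analysis import analyze_tuning, bar_profile, extract_trials, merge_logs
from .engine import (RenderTimeoutModel, TransportModel, frame_records_to_csv,
                     frame_statistics, run_experiment)
from .fictrac import write_fictrac
from .geometry import DisplayGeometry, visible_field
from .simfly import FlyModel
from .stimuli import build_protocol, randomize_blocks, trials_to_frame

__all__ = ["ExperimentConfig", "ValidationReport", "validate", "run",
           "default_config", "config_to_yaml", "config_from_yaml", "config_hash"]


@dataclass(frozen=True)
class ExperimentConfig:
    geometry: DisplayGeometry = field(default_factory=DisplayGeometry)
    protocol_kind: str = "temporal"
    n_blocks: int = 6
    startup_delay_ms: float = 10000.0
    protocol_seed: int = 0
    include_closed_loop: bool = True
    transport: TransportModel = field(
        default_factory=lambda: TransportModel(mean_latency_ms=1.0, jitter_ms=2.5))
    fly: FlyModel | None = field(default_factory=FlyModel)
    n_flies: int = 30
    analysis_window: int = 5
    render_timeout_every_n: int | None = None


def default_config() -> ExperimentConfig:
    """The standard temporal-frequency experiment on 30 synthetic flies."""
    return ExperimentConfig()


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(config: ExperimentConfig) -> ValidationReport:
    """Range and cross-field consistency checks; never raises."""
    rep = ValidationReport()
    g = config.geometry
    if config.protocol_kind not in ("temporal", "spatial", "bar"):
        rep.errors.append(f"unknown protocol kind {config.protocol_kind!r}")
    if config.n_blocks < 1:
        rep.errors.append("n_blocks must be >= 1")
    if config.n_flies < 0:
        rep.errors.append("n_flies must be >= 0")
    if config.analysis_window < 1 or config.analysis_window % 2 == 0:
        rep.errors.append("analysis window must be odd and >= 1")
    if config.transport.mean_latency_ms < 0 or config.transport.jitter_ms < 0:
        rep.errors.append("transport latencies must be >= 0")
    if config.startup_delay_ms < 0:
        rep.errors.append("startup_delay_ms must be >= 0")
    if config.protocol_kind == "temporal":
        from .stimuli import TEMPORAL_SPEEDS_DPS
        nyq = g.refresh_rate_hz / 2.0
        for speed in TEMPORAL_SPEEDS_DPS:
            tf = speed / 90.0
            if tf >= nyq:
                rep.warnings.append(
                    f"temporal frequency {tf:g} Hz is at or above half the display "
                    f"refresh rate ({g.refresh_rate_hz:g} Hz): the display flickers "
                    "and produces no net motion (the standard control condition)")
    if config.fly is not None and config.fly.camera_rate_hz < 2 * g.refresh_rate_hz:
        rep.warnings.append("camera rate below twice the display refresh rate")
    return rep


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_to_yaml(config: ExperimentConfig) -> str:
    doc = _to_jsonable(config)
    doc["fly"] = _to_jsonable(config.fly) if config.fly is not None else None
    return yaml.safe_dump(doc, sort_keys=True)


def config_from_yaml(text: str) -> ExperimentConfig:
    doc = yaml.safe_load(text)
    fly = doc.get("fly")
    return ExperimentConfig(
        geometry=DisplayGeometry(**doc.get("geometry", {})),
        protocol_kind=doc.get("protocol_kind", "temporal"),
        n_blocks=int(doc.get("n_blocks", 6)),
        startup_delay_ms=float(doc.get("startup_delay_ms", 10000.0)),
        protocol_seed=int(doc.get("protocol_seed", 0)),
        include_closed_loop=bool(doc.get("include_closed_loop", True)),
        transport=TransportModel(**doc.get("transport", {})),
        fly=FlyModel(**fly) if fly is not None else None,
        n_flies=int(doc.get("n_flies", 30)),
        analysis_window=int(doc.get("analysis_window", 5)),
        render_timeout_every_n=doc.get("render_timeout_every_n"),
    )


def config_hash(config: ExperimentConfig) -> str:
    """SHA-256 of the canonical JSON form of the config."""
    blob = json.dumps(_to_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run(config: ExperimentConfig, out_dir) -> dict:
    """Execute the configured experiment and write all artifacts.

    Writes, under ``out_dir``: the trial list, per-fly event logs and FicTrac
    files, frame records, the tuning curve, and ``manifest.json`` recording the
    config hash, seeds, package version and a SHA-256 per output file.
    Returns the manifest.
    """
    rep = validate(config)
    if not rep.ok:
        raise ValueError("invalid config:\n  " + "\n  ".join(rep.errors))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    protocol = build_protocol(config.protocol_kind, n_blocks=config.n_blocks,
                              startup_delay_ms=config.startup_delay_ms,
                              rng_seed=config.protocol_seed,
                              include_closed_loop=config.include_closed_loop)
    render_timeout = (RenderTimeoutModel(every_n=config.render_timeout_every_n)
                      if config.render_timeout_every_n else None)

    outputs: list[Path] = []
    runs = []
    n_runs = config.n_flies if config.fly is not None else 1
    for i in range(n_runs):
        trials = randomize_blocks(protocol, seed=config.protocol_seed + i)
        fly = (dataclasses.replace(config.fly, seed=config.fly.seed + i)
               if config.fly is not None else None)
        transport = dataclasses.replace(config.transport,
                                        seed=config.transport.seed + i)
        result = run_experiment(trials, config.geometry, transport, fly,
                                startup_delay_ms=config.startup_delay_ms,
                                render_timeout=render_timeout)
        if i == 0:
            p = out / "trials.csv"
            trials_to_frame(trials).to_csv(p, index=False)
            outputs.append(p)
            p = out / "frame_records_fly0.csv"
            frame_records_to_csv(result.frame_records, p)
            outputs.append(p)
        p = out / f"events_fly{i:02d}.csv"
        result.event_log.to_csv(p)
        outputs.append(p)
        if result.fictrac is not None:
            p = out / f"fictrac_fly{i:02d}.dat"
            write_fictrac(result.fictrac, p)
            outputs.append(p)
        runs.append(result)

    on_time, hist = frame_statistics(runs[0].frame_records,
                                     config.geometry.frame_interval_ms)
    manifest = {
        "package_version": __version__,
        "config_hash": config_hash(config),
        "config": _to_jsonable(config),
        "visible_field_deg": list(visible_field(config.geometry)),
        "on_time_fraction_fly0": on_time,
        "delay_histogram_fly0": {str(k): v for k, v in hist.items()},
    }
    if config.fly is not None:
        res = analyze_tuning(runs, window=config.analysis_window,
                             label=_axis_label(config.protocol_kind),
                             compute_traces=config.n_flies <= 5)
        p = out / "tuning_curve.csv"
        res.tuning.to_frame().to_csv(p, index=False)
        outputs.append(p)
        p = out / "per_fly_combined.csv"
        res.per_fly.to_csv(p, index=False)
        outputs.append(p)
        if len(res.traces):
            p = out / "population_traces.csv"
            res.traces.to_csv(p, index=False)
            outputs.append(p)
        manifest["n_closed_loop_excluded"] = res.n_closed_loop_excluded
        manifest["mean_forward_speed_mm_s"] = res.mean_forward_speed_mm_s

    manifest["outputs"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in outputs}
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, sort_keys=True)
    return manifest


def _axis_label(kind: str) -> str:
    return {"temporal": "temporal frequency (Hz)",
            "spatial": "spatial period (deg)",
            "bar": "bar speed (deg/s)"}.get(kind, kind)
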