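"""Session-log serialization, run configuration and the full pipeline.

Session logs are JSON Lines: a header object, then per trial a trial
object followed by one object per sample and per acquisition event.
JSON float round-tripping is exact, so write/read is lossless.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis
from .errors import ConfigError, MalformedLineError, SchemaMismatchError
from .exercise import (
    AcquisitionEvent,
    CavitySpec,
    ExerciseProtocol,
    ExerciseSetup,
    SessionLog,
    TrialLog,
    make_setup,
)
from .kinematics import default_geometry
from .metrics import metrics_table, write_metrics_csv
from .optics import CameraModel, OverlayEllipse

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "write_session",
    "read_session",
    "setup_from_config",
    "pipeline",
]

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# session JSONL
# --------------------------------------------------------------------------

def write_session(session: SessionLog, path) -> None:
    """Write a session log as JSON Lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        header = {"type": "header", "schema": SCHEMA_VERSION,
                  "subject_id": session.subject_id, "seed": session.seed,
                  "config_fingerprint": session.config_fingerprint,
                  "n_trials": len(session.trials)}
        fh.write(json.dumps(header) + "\n")
        for log in session.trials:
            proto = log.protocol
            fh.write(json.dumps({
                "type": "trial", "trial_index": log.trial_index,
                "protocol_id": proto.protocol_id, "order": list(proto.order),
                "time_limit_s": proto.time_limit_s,
                "overlay": [proto.overlay.semi_major, proto.overlay.semi_minor,
                            proto.overlay.orientation_deg],
            }) + "\n")
            for i in range(log.n_samples):
                fh.write(json.dumps({
                    "type": "sample", "trial": log.trial_index,
                    "t": float(log.t[i]),
                    "enc": [float(x) for x in log.theta[i]],
                    "pedal": bool(log.pedal[i]),
                }) + "\n")
            for ev in log.events:
                fh.write(json.dumps({
                    "type": "event", "trial": log.trial_index,
                    "target_id": ev.target_id, "t_press": ev.t_press,
                    "accuracy": ev.accuracy_at_press, "roll": ev.roll_at_press,
                    "timed_out": ev.timed_out,
                }) + "\n")


def read_session(path) -> SessionLog:
    """Read a session log written by :func:`write_session`.

    Raises
    ------
    SchemaMismatchError
        If the header declares an unsupported schema version.
    MalformedLineError
        With the 1-based line number of the first unparsable line.
    """
    path = Path(path)
    header = None
    trials: dict[int, dict] = {}
    order_seen: list[int] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                kind = obj["type"]
            except (json.JSONDecodeError, KeyError, TypeError) as e:
                raise MalformedLineError(lineno, str(e)) from e
            if kind == "header":
                if obj.get("schema") != SCHEMA_VERSION:
                    raise SchemaMismatchError(
                        f"schema {obj.get('schema')!r}, supported {SCHEMA_VERSION}")
                header = obj
            elif kind == "trial":
                try:
                    idx = obj["trial_index"]
                    trials[idx] = {
                        "protocol": ExerciseProtocol(
                            order=tuple(obj["order"]),
                            time_limit_s=obj["time_limit_s"],
                            overlay=OverlayEllipse(*obj["overlay"]),
                            protocol_id=obj["protocol_id"]),
                        "t": [], "enc": [], "pedal": [], "events": [],
                    }
                    order_seen.append(idx)
                except (KeyError, TypeError) as e:
                    raise MalformedLineError(lineno, str(e)) from e
            elif kind == "sample":
                try:
                    tr = trials[obj["trial"]]
                    tr["t"].append(obj["t"])
                    tr["enc"].append(obj["enc"])
                    tr["pedal"].append(obj["pedal"])
                except (KeyError, TypeError) as e:
                    raise MalformedLineError(lineno, str(e)) from e
            elif kind == "event":
                try:
                    trials[obj["trial"]]["events"].append(AcquisitionEvent(
                        target_id=obj["target_id"], t_press=obj["t_press"],
                        accuracy_at_press=obj["accuracy"],
                        roll_at_press=obj["roll"], timed_out=obj["timed_out"]))
                except (KeyError, TypeError) as e:
                    raise MalformedLineError(lineno, str(e)) from e
            else:
                raise MalformedLineError(lineno, f"unknown record type {kind!r}")
    if header is None:
        raise SchemaMismatchError("missing header line")
    logs = []
    for idx in order_seen:
        tr = trials[idx]
        logs.append(TrialLog(
            trial_index=idx, protocol=tr["protocol"],
            t=np.asarray(tr["t"], float),
            theta=np.asarray(tr["enc"], float).reshape(-1, 4),
            pedal=np.asarray(tr["pedal"], bool),
            events=tr["events"]))
    return SessionLog(subject_id=header["subject_id"], seed=header["seed"],
                      config_fingerprint=header["config_fingerprint"],
                      trials=logs)


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_DEFAULT_CONFIG = {
    "geometry": {
        "link_lengths": [150.0, 200.0, 200.0],
        "tool_length": 350.0,
        "optic_offset_deg": 30.0,
    },
    "camera": {
        "fov_deg": 70.0,
        "image_size": [640, 480],
        "near_limit_mm": 1.0,
    },
    "cavity": {"depth": 60.0, "fundal_width": 40.0, "ap_depth": 25.0},
    "overlay": {"semi_major": 40.0, "semi_minor": 28.0, "orientation_deg": 0.0},
    "protocol": {"time_limit_s": 30.0, "sample_dt": 0.02},
    "cohort": {"n_subjects": 80, "n_trials": 30},
}

_REQUIRED_BLOCKS = tuple(_DEFAULT_CONFIG)


@dataclass
class RunConfig:
    """Complete, serializable run configuration plus master seed."""

    blocks: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_CONFIG)))
    seed: int = 1

    @classmethod
    def default(cls, seed: int = 1) -> "RunConfig":
        return cls(seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        seed = int(data.pop("seed", 1))
        cfg = cls(seed=seed)
        for block, values in data.items():
            if block not in _REQUIRED_BLOCKS:
                raise ConfigError(f"unknown config block '{block}'")
            cfg.blocks[block].update(values or {})
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        data = {"seed": self.seed, **self.blocks}
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def validate(self) -> None:
        for block in _REQUIRED_BLOCKS:
            if block not in self.blocks or self.blocks[block] is None:
                raise ConfigError(f"missing config block '{block}'")

    def fingerprint(self) -> str:
        blob = json.dumps({"seed": self.seed, **self.blocks}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def setup_from_config(config: RunConfig) -> ExerciseSetup:
    """Build the exercise setup described by a run configuration."""
    from dataclasses import replace

    config.validate()
    g = config.blocks["geometry"]
    geom = default_geometry(optic_offset_deg=float(g["optic_offset_deg"]))
    geom = replace(geom,
                   link_lengths=tuple(float(x) for x in g["link_lengths"]),
                   tool_length=float(g["tool_length"]))
    c = config.blocks["camera"]
    cam = CameraModel(fov_deg=float(c["fov_deg"]),
                      image_size=tuple(int(x) for x in c["image_size"]),
                      optic_offset_deg=float(g["optic_offset_deg"]),
                      near_limit_mm=float(c["near_limit_mm"]))
    cav = CavitySpec(**{k: float(v) for k, v in config.blocks["cavity"].items()})
    ov = OverlayEllipse(**{k: float(v) for k, v in config.blocks["overlay"].items()})
    return make_setup(geom=geom, cam=cam, cavity=cav, overlay=ov,
                      sample_dt=float(config.blocks["protocol"]["sample_dt"]))


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def pipeline(config: RunConfig | None = None, outdir="results", seed: int | None = None,
             n_subjects: int | None = None, n_trials: int | None = None,
             write_logs: bool = False, progress: bool = False) -> dict:
    """simulate -> score -> analyze -> report, reproducibly from one seed.

    Returns a dict of output paths plus the in-memory metrics table and
    comparison tables.
    """
    from .agents import simulate_cohort  # local import to keep module load light

    config = config or RunConfig.default()
    if seed is not None:
        config.seed = int(seed)
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_sub = n_subjects or int(config.blocks["cohort"]["n_subjects"])
    n_tri = n_trials or int(config.blocks["cohort"]["n_trials"])
    setup = setup_from_config(config)
    sessions = simulate_cohort(n_sub, setup, seed=config.seed, n_trials=n_tri,
                               progress=progress)
    for s in sessions:
        s.config_fingerprint = config.fingerprint()
    if write_logs:
        logdir = outdir / "sessions"
        logdir.mkdir(exist_ok=True)
        for s in sessions:
            write_session(s, logdir / f"{s.subject_id}.jsonl")

    df = metrics_table(sessions, setup)
    paths = {"metrics": outdir / "metrics.csv"}
    write_metrics_csv(df, paths["metrics"])

    comparisons = {}
    pairs = [("initial_vs_final", analysis.INITIAL, analysis.FINAL),
             ("initial_vs_middle", analysis.INITIAL, analysis.MIDDLE),
             ("middle_vs_final", analysis.MIDDLE, analysis.FINAL)]
    report_parts = []
    for name, sa, sb in pairs:
        # subsets assume 30 trials; scale indices for short smoke runs
        if n_tri < max(sb.trial_indices):
            idx = {"initial": (1, 2), "middle": (n_tri // 2, n_tri // 2 + 1),
                   "final": (n_tri - 1, n_tri)}
            sa = analysis.SubsetSpec(sa.name, idx[sa.name])
            sb = analysis.SubsetSpec(sb.name, idx[sb.name])
        table = analysis.compare_subsets(df, sa, sb)
        comparisons[name] = table
        p = outdir / f"comparison_{name}.csv"
        table.to_csv(p, index=False)
        paths[name] = p
        report_parts.append(analysis.format_comparison(table))

    r, pmat = analysis.correlation_matrix(df)
    r.to_csv(outdir / "correlation_r.csv")
    pmat.to_csv(outdir / "correlation_p.csv")
    paths["correlation"] = outdir / "correlation_r.csv"

    lc_rows = []
    for m in analysis.ANALYSIS_METRICS[:5]:
        lc = analysis.learning_curve(df, m)
        lc_rows.append({"metric": m, "intercept": lc.intercept,
                        "slope": lc.slope, "r_squared": lc.r_squared})
    lc_df = pd.DataFrame(lc_rows)
    lc_df.to_csv(outdir / "learning_curves.csv", index=False)
    paths["learning_curves"] = outdir / "learning_curves.csv"

    report = "\n\n".join(
        [f"scopeskill pipeline report (seed={config.seed}, "
         f"n={n_sub} subjects x {n_tri} trials, config {config.fingerprint()})"]
        + report_parts
        + ["Log-fit slopes (mean ~ a + b*ln(trial)):\n" + lc_df.to_string(index=False)])
    paths["report"] = outdir / "report.txt"
    paths["report"].write_text(report + "\n", encoding="utf-8")

    return {"paths": paths, "metrics": df, "comparisons": comparisons,
            "correlation": (r, pmat), "learning_curves": lc_df,
            "sessions": sessions, "setup": setup}
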