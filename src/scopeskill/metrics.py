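"""Per-trial evaluation metrics.

Five indices are computed from each trial log, all from the resolved tip
poses: execution time (s), accuracy (% mean over the ten targets, with
timeouts counted as 0), orientation error (deg, mean wrapped difference
between the roll at acquisition and the target's nominal roll), tool-tip
trajectory length (mm) and total endoscope rotation (deg).  Two economy-
of-movement ratios normalize trajectory length and rotation by the ideal
values for the trial's target order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyLogError, UnresolvableSampleError
from .exercise import ExerciseProtocol, ExerciseSetup, SessionLog, TrialLog
from .kinematics import resolve_tip_batch, wrap_deg

__all__ = [
    "METRIC_COLUMNS",
    "TrialMetrics",
    "compute_trial_metrics",
    "ideal_economy_baseline",
    "metrics_table",
    "write_metrics_csv",
    "read_metrics_csv",
]

#: exact column set of the metrics CSV
METRIC_COLUMNS = [
    "subject_id", "trial_index", "exec_time_s", "accuracy_pct",
    "orientation_error_deg", "traj_length_mm", "total_rotation_deg",
    "econ_translation", "econ_rotation",
]


@dataclass(frozen=True)
class TrialMetrics:
    """The evaluation indices of one trial."""

    subject_id: str
    trial_index: int
    exec_time_s: float
    accuracy_pct: float
    orientation_error_deg: float
    traj_length_mm: float
    total_rotation_deg: float
    econ_translation: float
    econ_rotation: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_COLUMNS}


def ideal_economy_baseline(protocol: ExerciseProtocol,
                           setup: ExerciseSetup) -> tuple[float, float]:
    """Ideal translation (mm) and rotation (deg) for a target order.

    Sum of straight-line tip distances between consecutive ideal focusing
    poses (including the entry leg from the home pose) and of minimal
    wrapped roll changes along the same sequence.
    """
    tips = [np.asarray(setup.home_pose.position, float)]
    rolls = [float(setup.home_pose.roll)]
    for tid in protocol.order:
        p = setup.ideal_poses[tid]
        tips.append(np.asarray(p.position, float))
        rolls.append(float(p.roll))
    tips = np.stack(tips)
    translation = float(np.linalg.norm(np.diff(tips, axis=0), axis=1).sum())
    rolls = np.asarray(rolls)
    rotation = float(np.abs(wrap_deg(np.diff(rolls))).sum())
    return translation, rotation


def compute_trial_metrics(log: TrialLog, setup: ExerciseSetup,
                          subject_id: str = "") -> TrialMetrics:
    """Compute all indices of one trial from its raw sample log."""
    if log.t is None or len(log.t) == 0:
        raise EmptyLogError("trial log has no samples")
    try:
        tips, rolls, _ = resolve_tip_batch(log.theta, setup.geom)
    except Exception as e:  # pinpoint the offending sample for diagnostics
        for i, row in enumerate(log.theta):
            try:
                resolve_tip_batch(row[None, :], setup.geom)
            except Exception:
                raise UnresolvableSampleError(i, str(e)) from e
        raise

    exec_time = float(log.events[-1].t_press - log.t[0]) if log.events else 0.0
    if log.events:
        acc = float(np.mean([ev.accuracy_at_press for ev in log.events]))
        errs = [abs(wrap_deg(ev.roll_at_press
                             - setup.target_by_id(ev.target_id).nominal_roll))
                for ev in log.events]
        orient = float(np.mean(errs))
    else:
        acc, orient = 0.0, 0.0

    traj = float(np.linalg.norm(np.diff(tips, axis=0), axis=1).sum())
    rot = float(np.abs(wrap_deg(np.diff(rolls))).sum())
    base_t, base_r = ideal_economy_baseline(log.protocol, setup)
    return TrialMetrics(
        subject_id=subject_id,
        trial_index=log.trial_index,
        exec_time_s=exec_time,
        accuracy_pct=acc,
        orientation_error_deg=orient,
        traj_length_mm=traj,
        total_rotation_deg=rot,
        econ_translation=traj / base_t,
        econ_rotation=rot / base_r,
    )


def metrics_table(sessions: list[SessionLog], setup: ExerciseSetup) -> pd.DataFrame:
    """One row per (subject, trial), in the exact metrics CSV column set."""
    rows = [compute_trial_metrics(log, setup, subject_id=s.subject_id).as_dict()
            for s in sessions for log in s.trials]
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    """Write the metrics table (comma-separated, '.' decimals, header)."""
    df.to_csv(path, index=False, columns=METRIC_COLUMNS)


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics CSV missing columns: {missing}")
    return df[METRIC_COLUMNS]
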