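"""Optional figures: learning-curve boxes and tip trajectories.

Kept deliberately small; all statistics live in :mod:`scopeskill.analysis`.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .analysis import learning_curve
from .kinematics import resolve_tip_batch

__all__ = ["plot_learning_curve", "plot_trajectory"]


def plot_learning_curve(df, metric: str, path=None, ax=None):
    """Per-trial median/IQR band with the mean and its log fit."""
    lc = learning_curve(df, metric)
    pt = lc.per_trial
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    ax.fill_between(pt.trial_index, pt.q1, pt.q3, alpha=0.25, label="IQR")
    ax.plot(pt.trial_index, pt["median"], lw=1.2, label="median")
    ax.plot(pt.trial_index, pt["mean"], "o", ms=3, label="mean")
    x = np.linspace(1, pt.trial_index.max(), 100)
    ax.plot(x, lc.intercept + lc.slope * np.log(x), "--",
            label=f"a+b ln(trial), b={lc.slope:.2f}")
    ax.set_xlabel("trial")
    ax.set_ylabel(metric)
    ax.legend(fontsize=7)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_trajectory(log, setup, path=None, ax=None):
    """Tip trajectory of one trial projected on the coronal (x-z) plane."""
    tips, _, _ = resolve_tip_batch(log.theta, setup.geom)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(tips[:, 0], tips[:, 2], lw=0.6)
    for t in setup.targets:
        ax.plot(t.center[0], t.center[2], "ks", ms=4)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_title(f"trial {log.trial_index}")
    ax.set_aspect("equal")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
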