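"""Learning-curve statistics: subset comparisons, correlations, curve fits.

The study design compares the initial (trials 1-3), middle (14-16) and
final (28-30) subsets of a 30-trial session.  For each metric, one value
per subject per subset (the mean over its three trials) feeds a paired
two-sided t-test; the report row carries means, standard deviations, the
gain ratio and difference, the 95% CI of the mean paired difference, the
post-hoc power of the performed test at the observed standardized effect,
and the sample size required to reach a target power at that effect.

Power and sample size use the noncentral-t distribution of the paired
t statistic: with standardized paired effect d = mean(diff)/sd(diff) and
n subjects, the statistic is noncentral t with df = n-1 and noncentrality
d*sqrt(n); power is the probability mass beyond the two-sided critical
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingTrialsError, NTooSmallError, ZeroVarianceError

__all__ = [
    "SubsetSpec",
    "INITIAL",
    "MIDDLE",
    "FINAL",
    "ANALYSIS_METRICS",
    "CORR_METRICS",
    "subject_subset_means",
    "effect_summary",
    "paired_power",
    "paired_sample_size",
    "compare_subsets",
    "correlation_matrix",
    "learning_curve",
    "LearningCurveSummary",
    "format_comparison",
]


@dataclass(frozen=True)
class SubsetSpec:
    """A named subset of trial indices."""

    name: str
    trial_indices: tuple[int, ...]

    def __post_init__(self):
        if len(set(self.trial_indices)) != len(self.trial_indices):
            raise ValueError("duplicate trial indices")


INITIAL = SubsetSpec("initial", (1, 2, 3))
MIDDLE = SubsetSpec("middle", (14, 15, 16))
FINAL = SubsetSpec("final", (28, 29, 30))

#: metric columns entering the subset-comparison tables (7 rows)
ANALYSIS_METRICS = [
    "exec_time_s", "accuracy_pct", "orientation_error_deg",
    "traj_length_mm", "total_rotation_deg", "econ_translation",
    "econ_rotation",
]

#: the five indices of the correlation matrix (ET, AC, EO, TT, TR)
CORR_METRICS = [
    "exec_time_s", "accuracy_pct", "orientation_error_deg",
    "traj_length_mm", "total_rotation_deg",
]


def subject_subset_means(df: pd.DataFrame, subset: SubsetSpec,
                         metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-subject means over a subset's trials (one row per subject).

    Raises :class:`MissingTrialsError` if any subject lacks a subset trial.
    """
    metrics = metrics or ANALYSIS_METRICS
    sub = df[df["trial_index"].isin(subset.trial_indices)]
    counts = sub.groupby("subject_id")["trial_index"].nunique()
    expected = len(subset.trial_indices)
    all_subjects = df["subject_id"].unique()
    bad = sorted(set(all_subjects) - set(counts[counts == expected].index))
    if bad:
        raise MissingTrialsError(bad)
    return sub.groupby("subject_id")[metrics].mean().sort_index()


def effect_summary(mean_a: float, mean_b: float) -> tuple[float, float]:
    """Gain ratio ``mean_a / mean_b`` and difference ``mean_a - mean_b``."""
    if mean_b == 0.0:
        raise ZeroDivisionError("ratio undefined: second mean is zero")
    return mean_a / mean_b, mean_a - mean_b


def paired_power(effect_size: float, n: int, alpha: float = 0.05) -> float:
    """Two-sided power of the paired t-test at standardized effect ``d``.

    ``effect_size`` is mean(diff)/sd(diff); ``n`` the number of pairs.
    """
    if n < 2:
        return float(alpha)
    df = n - 1
    nc = abs(effect_size) * math.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    upper = stats.nct.sf(tcrit, df, nc)
    lower = stats.nct.cdf(-tcrit, df, nc)
    if not np.isfinite(upper):   # scipy can return nan at extreme nc
        upper = 1.0 if nc > tcrit else 0.0
    if not np.isfinite(lower):
        lower = 0.0
    return float(min(1.0, max(0.0, upper + lower)))


def paired_sample_size(effect_size: float, alpha: float = 0.05,
                       target_power: float = 0.8,
                       n_max: int = 10_000_000) -> float:
    """Smallest n of pairs reaching ``target_power``; ``inf`` if effect is 0."""
    if effect_size == 0.0 or not np.isfinite(effect_size):
        return math.inf
    lo, hi = 2, 2
    while paired_power(effect_size, hi, alpha) < target_power:
        hi *= 2
        if hi > n_max:
            return math.inf
    while lo < hi:
        mid = (lo + hi) // 2
        if paired_power(effect_size, mid, alpha) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return float(lo)


def compare_subsets(df: pd.DataFrame, subset_a: SubsetSpec = INITIAL,
                    subset_b: SubsetSpec = FINAL, alpha: float = 0.05,
                    target_power: float = 0.8,
                    metrics: list[str] | None = None,
                    holm: bool = False) -> pd.DataFrame:
    """Paired subset comparison: one row per metric.

    Columns: metric, mean_a, std_a, mean_b, std_b, ratio, diff, t_stat,
    p_value, ci_low, ci_high, power, sample_size, h.  Per-subject subset
    means feed the paired test; stds are across subjects (ddof=1).
    """
    metrics = metrics or ANALYSIS_METRICS
    A = subject_subset_means(df, subset_a, metrics)
    B = subject_subset_means(df, subset_b, metrics)
    if not A.index.equals(B.index):
        raise MissingTrialsError(sorted(set(A.index) ^ set(B.index)))
    n = len(A)
    if n < 3:
        raise NTooSmallError(f"need >= 3 subjects, got {n}")

    rows = []
    for m in metrics:
        a, b = A[m].to_numpy(), B[m].to_numpy()
        d = a - b
        dbar = float(d.mean())
        sd = float(d.std(ddof=1))
        ratio, diff = effect_summary(float(a.mean()), float(b.mean()))
        dof = n - 1
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, dof)
        if sd == 0.0:
            t_stat = 0.0 if dbar == 0.0 else math.copysign(math.inf, dbar)
            p = 1.0 if dbar == 0.0 else 0.0
            ci_low = ci_high = dbar
            eff = 0.0 if dbar == 0.0 else math.inf
        else:
            se = sd / math.sqrt(n)
            t_stat = dbar / se
            p = 2.0 * stats.t.sf(abs(t_stat), dof)
            ci_low, ci_high = dbar - tcrit * se, dbar + tcrit * se
            eff = dbar / sd
        rows.append({
            "metric": m,
            "mean_a": float(a.mean()), "std_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()), "std_b": float(b.std(ddof=1)),
            "ratio": ratio, "diff": diff,
            "t_stat": float(t_stat), "p_value": float(p),
            "ci_low": float(ci_low), "ci_high": float(ci_high),
            "power": paired_power(eff if np.isfinite(eff) else 50.0, n, alpha),
            "sample_size": paired_sample_size(eff, alpha, target_power),
        })
    out = pd.DataFrame(rows)
    pvals = out["p_value"].to_numpy()
    if holm:
        order = np.argsort(pvals)
        adj = np.empty_like(pvals)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (len(pvals) - rank) * pvals[idx])
            adj[idx] = min(1.0, running)
        out["p_value_adj"] = adj
        out["h"] = (adj < alpha).astype(int)
    else:
        out["h"] = (pvals < alpha).astype(int)
    out.attrs["subset_a"] = subset_a.name
    out.attrs["subset_b"] = subset_b.name
    out.attrs["n_subjects"] = n
    return out


def correlation_matrix(df: pd.DataFrame,
                       metrics: list[str] | None = None):
    """Pearson correlations over all (subject, trial) rows.

    Returns ``(r, p)``: symmetric DataFrames with unit/zero diagonals.
    Raises :class:`ZeroVarianceError` naming constant metrics.
    """
    metrics = metrics or CORR_METRICS
    if len(df) < 3:
        raise NTooSmallError("need >= 3 rows")
    X = df[metrics].to_numpy(float)
    const = [m for j, m in enumerate(metrics) if np.std(X[:, j]) == 0.0]
    if const:
        raise ZeroVarianceError(f"constant metrics: {const}")
    k = len(metrics)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            rr, pp = stats.pearsonr(X[:, i], X[:, j])
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    return (pd.DataFrame(r, index=metrics, columns=metrics),
            pd.DataFrame(p, index=metrics, columns=metrics))


@dataclass
class LearningCurveSummary:
    """Per-trial descriptive statistics and the logarithmic trend fit."""

    metric: str
    per_trial: pd.DataFrame     # trial_index, mean, median, q1, q3, iqr
    intercept: float            # a in mean ~ a + b*ln(trial)
    slope: float                # b; sign is the headline trend indicator
    r_squared: float


def learning_curve(df: pd.DataFrame, metric: str) -> LearningCurveSummary:
    """Cross-subject learning curve of one metric with an a + b*ln(trial) fit."""
    g = df.groupby("trial_index")[metric]
    per_trial = pd.DataFrame({
        "mean": g.mean(), "median": g.median(),
        "q1": g.quantile(0.25), "q3": g.quantile(0.75),
    }).reset_index()
    per_trial["iqr"] = per_trial["q3"] - per_trial["q1"]
    if per_trial["trial_index"].nunique() < 2:
        raise ValueError("need >= 2 distinct trial indices")
    x = np.log(per_trial["trial_index"].to_numpy(float))
    y = per_trial["mean"].to_numpy(float)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = intercept + slope * x
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return LearningCurveSummary(metric=metric, per_trial=per_trial,
                                intercept=float(intercept), slope=float(slope),
                                r_squared=float(r2))


def format_comparison(table: pd.DataFrame) -> str:
    """Plain-text rendering of a subset-comparison table."""
    name = f"{table.attrs.get('subset_a', 'A')} vs {table.attrs.get('subset_b', 'B')}"
    lines = [f"Comparison: {name} (n = {table.attrs.get('n_subjects', '?')})",
             f"{'metric':<22}{'meanA':>10}{'stdA':>9}{'meanB':>10}{'stdB':>9}"
             f"{'A/B':>7}{'A-B':>10}{'t':>8}{'p':>10}{'power':>7}{'n_req':>7}{'h':>3}"]
    for _, r in table.iterrows():
        nreq = "inf" if not np.isfinite(r.sample_size) else f"{int(r.sample_size)}"
        lines.append(
            f"{r.metric:<22}{r.mean_a:>10.3f}{r.std_a:>9.3f}{r.mean_b:>10.3f}"
            f"{r.std_b:>9.3f}{r.ratio:>7.3f}{r['diff']:>10.3f}{r.t_stat:>8.2f}"
            f"{r.p_value:>10.2e}{r.power:>7.3f}{nreq:>7}{int(r.h):>3}")
    return "\n".join(lines)
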