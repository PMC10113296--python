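"""Synthetic-surgeon cohort simulator.

Generates encoder-level session logs whose trial-over-trial statistics
show the qualitative structure of real training cohorts: logarithmic-
looking learning curves, shrinking dispersion, and strong positive
correlation between execution time, path length and total rotation.

The generative model is deliberately different from the analysis model:
each skill parameter follows an exponential approach to an asymptote,

    level_m(trial) = c_m + (a_m - c_m) * exp(-k_m * (trial - 1)),

while the analysis layer fits ``a + b*ln(trial)`` to the cohort means.
Using distinct generative and fitted forms avoids validating the curve
fit against itself.

Per target the agent: waits a reaction time, executes a minimum-jerk
reach in shaft space (pan, tilt, insertion depth, roll) toward the
target's ideal focusing pose plus a terminal aiming error, overlays
smooth sinusoidal jitter, then makes corrective sub-movements until its
*perceived* focus score (a fast sampled-containment score plus a
per-target perceptual error of scale ``press_noise``) reaches 100, at
which point it presses the pedal.  If the per-target window elapses
first, the target times out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .exercise import ExerciseProtocol, ExerciseSetup, SessionLog, make_orders, run_trial
from .kinematics import pose_from_shaft
from .optics import focus_score_fast

__all__ = [
    "METRIC_NAMES",
    "AgentParams",
    "CohortPriors",
    "default_priors",
    "sample_cohort",
    "LearningAgent",
    "PerfectAgent",
    "IdleAgent",
    "plan_motion",
    "simulate_session",
    "simulate_cohort",
]

METRIC_NAMES = ("time", "path_jitter", "roll_jitter", "aim_error", "press_noise")

_ANGLE_LEVER_MM = 22.0   # approximate tip lever arm for pan/tilt jitter scaling


@dataclass(frozen=True)
class AgentParams:
    """Skill parameters of one synthetic subject.

    For each skill channel ``m`` the triple ``(a_m, c_m, k_m)`` gives the
    initial level, the asymptote and the learning rate of the exponential-
    approach schedule.  Units: time s (per-target movement budget),
    path_jitter mm (tip-space tremor amplitude), roll_jitter deg,
    aim_error rad (terminal aiming spread), press_noise score points.
    """

    subject_id: str
    experience_class: str
    a: dict[str, float]
    c: dict[str, float]
    k: dict[str, float]

    def __post_init__(self):
        for m in METRIC_NAMES:
            if not (self.a[m] >= self.c[m] > 0.0):
                raise ConfigError(f"need a >= c > 0 for '{m}'")
            if self.k[m] <= 0.0:
                raise ConfigError(f"need k > 0 for '{m}'")

    def level(self, m: str, trial: int) -> float:
        """Exponential-approach learning schedule, trial >= 1."""
        return self.c[m] + (self.a[m] - self.c[m]) * math.exp(-self.k[m] * (trial - 1))


# --------------------------------------------------------------------------
# cohort priors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortPriors:
    """Sampling priors per experience class.

    ``classes`` maps class label -> proportion; ``params`` maps class ->
    skill channel -> (a_mean, a_sd, c_mean, c_sd); ``k_mean``/``k_sd``
    are shared across channels.
    """

    classes: dict[str, float]
    params: dict[str, dict[str, tuple[float, float, float, float]]]
    k_mean: float = 0.13
    k_sd: float = 0.035

    def __post_init__(self):
        tot = sum(self.classes.values())
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ConfigError("class proportions must sum to 1")
        for cls, chans in self.params.items():
            for m, (am, asd, cm, csd) in chans.items():
                if min(am, cm) <= 0 or min(asd, csd) < 0:
                    raise ConfigError(f"non-positive prior for {cls}/{m}")
        if self.k_mean <= 0 or self.k_sd < 0:
            raise ConfigError("non-positive k prior")


def default_priors() -> CohortPriors:
    """Priors emulating a mixed cohort of gynaecologists (novice to expert)."""
    p = {
        "novice": {
            "time": (13.0, 2.5, 6.5, 1.0),
            "path_jitter": (2.4, 0.6, 0.8, 0.2),
            "roll_jitter": (2.0, 0.5, 0.7, 0.2),
            "aim_error": (0.055, 0.012, 0.015, 0.004),
            "press_noise": (13.0, 3.0, 2.5, 0.7),
        },
        "intermediate": {
            "time": (10.5, 2.0, 5.8, 0.9),
            "path_jitter": (2.0, 0.5, 0.75, 0.2),
            "roll_jitter": (1.7, 0.4, 0.65, 0.15),
            "aim_error": (0.045, 0.010, 0.013, 0.003),
            "press_noise": (11.0, 2.5, 2.2, 0.6),
        },
        "expert": {
            "time": (8.0, 1.5, 5.2, 0.8),
            "path_jitter": (1.5, 0.4, 0.7, 0.15),
            "roll_jitter": (1.3, 0.3, 0.6, 0.15),
            "aim_error": (0.032, 0.008, 0.012, 0.003),
            "press_noise": (8.0, 2.0, 2.0, 0.5),
        },
    }
    return CohortPriors(
        classes={"novice": 0.45, "intermediate": 0.35, "expert": 0.20},
        params=p,
    )


def _draw_positive(rng: np.random.Generator, mean: float, sd: float,
                   lo: float = 1e-6) -> float:
    """Normal draw truncated (by redraw) to be positive."""
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > lo:
            return float(x)
    return float(max(lo, mean))


def sample_cohort(n: int, priors: CohortPriors | None = None,
                  rng: np.random.Generator | int = 0) -> list[AgentParams]:
    """Draw ``n`` subjects; experience classes in the configured proportions."""
    if n < 1:
        raise ConfigError("need n >= 1")
    priors = priors or default_priors()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = list(priors.classes)
    counts = [int(round(priors.classes[c] * n)) for c in labels]
    while sum(counts) < n:
        counts[0] += 1
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    assignment = [lab for lab, cnt in zip(labels, counts) for _ in range(cnt)]
    rng.shuffle(assignment)

    cohort = []
    for i, cls in enumerate(assignment):
        a, c, k = {}, {}, {}
        for m in METRIC_NAMES:
            am, asd, cm, csd = priors.params[cls][m]
            cv = _draw_positive(rng, cm, csd)
            av = _draw_positive(rng, am, asd)
            a[m] = max(av, cv * 1.05)
            c[m] = cv
            k[m] = _draw_positive(rng, priors.k_mean, priors.k_sd, lo=0.04)
        cohort.append(AgentParams(subject_id=f"S{i + 1:03d}",
                                  experience_class=cls, a=a, c=c, k=k))
    return cohort


# --------------------------------------------------------------------------
# motion planning
# --------------------------------------------------------------------------

def _minjerk(s: np.ndarray) -> np.ndarray:
    return 10.0 * s ** 3 - 15.0 * s ** 4 + 6.0 * s ** 5


class _Jitter:
    """Smooth zero-mean jitter: two sinusoids per channel, continuous in t."""

    def __init__(self, amps, rng: np.random.Generator):
        self.amps = np.asarray(amps, float)              # (4,)
        self.freq = rng.uniform(0.7, 2.3, size=(4, 2))   # Hz
        self.phase = rng.uniform(0.0, 2.0 * np.pi, size=(4, 2))
        self.w = np.array([0.65, 0.35])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(t)
        arg = 2.0 * np.pi * self.freq[None, :, :] * t[:, None, None] \
            + self.phase[None, :, :]
        return (np.sin(arg) * self.w[None, None, :]).sum(axis=2) * self.amps[None, :]


def plan_motion(q_start, target, setup: ExerciseSetup, params: AgentParams,
                trial_index: int, rng: np.random.Generator,
                time_limit_s: float = 30.0):
    """Plan one target acquisition.

    Returns ``(times, qs, press_index)`` in the agent contract of
    :func:`scopeskill.exercise.run_trial`: times (s, strictly increasing,
    starting at one sample period), qs ``(n, 4)`` shaft-space samples and
    the press sample index (``None`` on timeout).
    """
    dt = setup.sample_dt
    lvl = {m: params.level(m, trial_index) for m in METRIC_NAMES}
    q_star = setup.ideal_q(target.id)
    q_start = np.asarray(q_start, float)

    jit_ang = lvl["path_jitter"] / _ANGLE_LEVER_MM
    jitter = _Jitter([jit_ang, jit_ang, 0.5 * lvl["path_jitter"],
                      lvl["roll_jitter"]], rng)

    def draw_offset(scale=1.0):
        return np.array([
            rng.normal(0.0, lvl["aim_error"] * scale),
            rng.normal(0.0, lvl["aim_error"] * scale),
            rng.normal(0.0, 40.0 * lvl["aim_error"] * scale),
            rng.normal(0.0, 2.5 * lvl["roll_jitter"] * scale),
        ])

    threshold = min(100.0, 100.0 - abs(rng.normal(0.0, lvl["press_noise"])))
    threshold = max(threshold, 55.0)

    reaction = rng.uniform(0.25, 0.6)
    T_reach = max(0.8, 0.8 * lvl["time"] * rng.lognormal(0.0, 0.2))
    offset = draw_offset()

    times_parts, q_parts = [], []
    t_rel = 0.0
    q_from = q_start.copy()
    press_idx = None
    n_emitted = 0
    check_gate = reaction + T_reach          # perception starts on arrival
    next_check = check_gate
    check_dt = 0.12

    def emit_segment(q_to, T_seg, scan: bool):
        """Append one min-jerk segment; return True if pressed."""
        nonlocal t_rel, q_from, press_idx, n_emitted, next_check
        n = max(1, int(round(T_seg / dt)))
        ts = t_rel + dt * np.arange(1, n + 1)
        s = _minjerk(np.arange(1, n + 1) / n)
        base = q_from[None, :] + (np.asarray(q_to) - q_from)[None, :] * s[:, None]
        base[:, 2] = np.maximum(base[:, 2], 0.5)   # never retract past fulcrum
        qs = base + jitter(ts)
        qs[:, 2] = np.maximum(qs[:, 2], 0.5)
        if scan and press_idx is None:
            for i in range(n):
                if ts[i] + 1e-12 < next_check:
                    continue
                next_check = ts[i] + check_dt
                pose = pose_from_shaft(qs[i, 0], qs[i, 1], qs[i, 2], qs[i, 3],
                                       setup.geom)
                score = focus_score_fast(pose, target, setup.cam, setup.overlay)
                if score >= threshold:
                    press_idx = n_emitted + i
                    ts = ts[: i + 1]
                    qs = qs[: i + 1]
                    break
        times_parts.append(ts)
        q_parts.append(qs)
        n_emitted += len(ts)
        t_rel = float(ts[-1])
        q_from = base[min(len(ts), n) - 1].copy()
        return press_idx is not None

    # reaction hold, then reach, then corrective sub-movements
    emit_segment(q_start, reaction, scan=False)
    pressed = emit_segment(q_star + offset, T_reach, scan=True)
    while not pressed and t_rel < time_limit_s + 1.0:
        if rng.uniform() < 0.18:
            offset = draw_offset(scale=rng.uniform(0.5, 1.0))   # re-aim afresh
        else:
            offset = offset * rng.uniform(0.30, 0.65)           # converge
        T_corr = rng.uniform(0.5, 1.0)
        pressed = emit_segment(q_star + offset, T_corr, scan=True)

    times = np.concatenate(times_parts)
    qs = np.concatenate(q_parts, axis=0)
    return times, qs, press_idx


# --------------------------------------------------------------------------
# agents
# --------------------------------------------------------------------------

class LearningAgent:
    """Synthetic surgeon driven by :func:`plan_motion`."""

    def __init__(self, params: AgentParams):
        self.params = params

    def play_target(self, q_start, target, setup, protocol, trial_index, rng):
        return plan_motion(q_start, target, setup, self.params, trial_index,
                           rng, time_limit_s=protocol.time_limit_s)


class PerfectAgent:
    """Oracle agent: teleports to each target's ideal pose and presses."""

    def play_target(self, q_start, target, setup, protocol, trial_index, rng):
        dt = setup.sample_dt
        q_star = setup.ideal_q(target.id)
        times = np.array([dt, 2.0 * dt])
        qs = np.stack([q_star, q_star])
        return times, qs, 1


class IdleAgent:
    """Never moves, never presses: every target times out."""

    def play_target(self, q_start, target, setup, protocol, trial_index, rng):
        n = int(math.ceil(protocol.time_limit_s / 0.5))
        times = 0.5 * np.arange(1, n + 1)
        qs = np.tile(np.asarray(q_start, float), (n, 1))
        return times, qs, None


# --------------------------------------------------------------------------
# sessions and cohorts
# --------------------------------------------------------------------------

def make_protocols(n_trials: int, order_seed: int,
                   time_limit_s: float = 30.0) -> list[ExerciseProtocol]:
    """Round-robin assignment of the five target orders to trials."""
    orders = make_orders(order_seed)
    return [ExerciseProtocol(order=orders[i % len(orders)],
                             time_limit_s=time_limit_s, protocol_id=i % len(orders))
            for i in range(n_trials)]


def simulate_session(params: AgentParams, protocols, setup: ExerciseSetup,
                     rng: np.random.Generator | int,
                     config_fingerprint: str = "") -> SessionLog:
    """Simulate one subject's full session (one trial per protocol)."""
    if not isinstance(rng, np.random.Generator):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    agent = LearningAgent(params)
    trials = []
    for i, proto in enumerate(protocols, start=1):
        trials.append(run_trial(agent, proto, setup, rng, trial_index=i))
    return SessionLog(subject_id=params.subject_id, seed=seed,
                      config_fingerprint=config_fingerprint, trials=trials)


def simulate_cohort(n_subjects: int, setup: ExerciseSetup, seed: int = 1,
                    n_trials: int = 30, priors: CohortPriors | None = None,
                    progress: bool = False) -> list[SessionLog]:
    """Simulate a full cohort, reproducibly from one master seed."""
    ss = np.random.SeedSequence(seed)
    cohort_seed, order_seed, *subject_seeds = ss.spawn(2 + n_subjects)
    cohort = sample_cohort(n_subjects, priors,
                           np.random.default_rng(cohort_seed))
    protocols = make_protocols(n_trials,
                               int(order_seed.generate_state(1)[0] % (2 ** 31)))
    sessions = []
    for params, sseq in zip(cohort, subject_seeds):
        rng = np.random.default_rng(sseq)
        sessions.append(simulate_session(params, protocols, setup, rng,
                                         config_fingerprint=f"seed={seed}"))
        if progress:
            print(f"  simulated {params.subject_id}", flush=True)
    return sessions
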