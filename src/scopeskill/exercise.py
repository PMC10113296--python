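"""The 30-degree camera-navigation exercise.

Ten ring targets sit on the walls of a simplified uterine cavity (a
triangular prism: narrow at the internal os, widening toward the fundus).
A trial activates the targets in a prescribed order; the trainee steers
the scope (pivoting about the fulcrum, inserting/withdrawing, rolling the
oblique optic) until the on-screen reticle lies inside the target ring,
then presses the pedal.  Each target has a 30 s window; a miss is logged
as a timeout with zero accuracy.

This module provides the cavity and target layout, a numerically-searched
ideal focusing pose per target (which also defines the target's nominal
roll), the target-order generator, and the trial engine that turns an
agent's motion into a complete encoder-level :class:`TrialLog`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .errors import AgentStallError, ConfigError
from .kinematics import (
    ArmGeometry,
    EncoderReading,
    TipPose,
    angles_from_shaft,
    default_geometry,
    encoders_from_shaft_batch,
    pose_from_shaft,
    resolve_tip_pose,
    roll_for_view,
    shaft_from_angles,
)
from .optics import (
    CameraModel,
    NotVisibleError,
    ObliqueDegenerateError,
    OverlayEllipse,
    TargetMarker,
    accuracy_score,
    is_focused,
    project_ring,
)

__all__ = [
    "CavitySpec",
    "ExerciseProtocol",
    "SampleRecord",
    "AcquisitionEvent",
    "TrialLog",
    "SessionLog",
    "ExerciseSetup",
    "make_target_layout",
    "make_orders",
    "ideal_focus_pose",
    "make_setup",
    "run_trial",
]

ANATOMICAL_LABELS = (
    "fundus", "left cornua", "right cornua", "left ostium", "right ostium",
    "anterior wall", "posterior wall", "left lateral wall",
    "right lateral wall", "isthmus",
)


@dataclass(frozen=True)
class CavitySpec:
    """Triangular-prism uterine cavity model.

    The cavity occupies ``0 <= z <= depth`` with the fulcrum at the origin
    (internal os); the coronal cross-section is a triangle whose width
    grows linearly from 0 at the os to ``fundal_width`` at the fundus;
    anteroposterior extent is ``ap_depth`` (|y| <= ap_depth/2).
    """

    depth: float = 60.0          # fundus-isthmus, mm
    fundal_width: float = 40.0   # inter-cornual, mm
    ap_depth: float = 25.0       # anteroposterior, mm

    def __post_init__(self):
        if min(self.depth, self.fundal_width, self.ap_depth) <= 0:
            raise ConfigError("cavity dimensions must be positive")

    def margin(self, p) -> float:
        """Signed distance-like margin; positive inside the cavity."""
        p = np.asarray(p, float)
        half_w = (p[2] / self.depth) * self.fundal_width / 2.0
        return float(min(p[2], self.depth - p[2],
                         self.ap_depth / 2.0 - abs(p[1]),
                         half_w - abs(p[0])))

    def contains(self, p, tol: float = 0.0) -> bool:
        return self.margin(p) >= -tol


def make_target_layout(cavity: CavitySpec | None = None) -> list[TargetMarker]:
    """Place the ten ring targets at their anatomical stations.

    Centres and normals are defined on (or just inside) the cavity walls;
    left/right pairs are exact sagittal mirrors.  Nominal rolls are filled
    in later by :func:`make_setup` from the per-target ideal focusing pose.
    """
    cav = cavity or CavitySpec()
    sx = cav.fundal_width / 40.0   # scale factors for non-default cavities
    sy = cav.ap_depth / 25.0
    sz = cav.depth / 60.0

    def t(i, label, c, n):
        return TargetMarker(id=i, center=np.array(c, float), normal=np.array(n, float),
                            anatomical_label=label)

    targets = [
        t(1, "fundus", (0.0, 0.0, 58.0 * sz), (0.0, 0.0, -1.0)),
        t(2, "left cornua", (-14.0 * sx, 0.0, 54.0 * sz), (14.0, 0.0, -13.0)),
        t(3, "right cornua", (14.0 * sx, 0.0, 54.0 * sz), (-14.0, 0.0, -13.0)),
        t(4, "left ostium", (-17.0 * sx, 0.0, 56.5 * sz), (17.0, 0.0, -15.0)),
        t(5, "right ostium", (17.0 * sx, 0.0, 56.5 * sz), (-17.0, 0.0, -15.0)),
        t(6, "anterior wall", (0.0, 12.0 * sy, 34.0 * sz), (0.0, -1.0, 0.1)),
        t(7, "posterior wall", (0.0, -12.0 * sy, 34.0 * sz), (0.0, 1.0, 0.1)),
        t(8, "left lateral wall", (-11.0 * sx, 0.0, 36.0 * sz), (3.0, 0.0, 1.0)),
        t(9, "right lateral wall", (11.0 * sx, 0.0, 36.0 * sz), (-3.0, 0.0, 1.0)),
        t(10, "isthmus", (0.0, 11.0 * sy, 11.0 * sz), (0.0, -1.0, 0.3)),
    ]
    return targets


def make_orders(seed: int, n_orders: int = 5, n_targets: int = 10) -> list[tuple[int, ...]]:
    """Deterministic set of distinct target orders (one per protocol)."""
    rng = np.random.default_rng(seed)
    orders: list[tuple[int, ...]] = []
    while len(orders) < n_orders:
        perm = tuple(int(x) for x in rng.permutation(n_targets) + 1)
        if perm not in orders:
            orders.append(perm)
    return orders


@dataclass(frozen=True)
class ExerciseProtocol:
    """One trial's protocol: target order, per-target clock, difficulty."""

    order: tuple[int, ...]
    time_limit_s: float = 30.0
    overlay: OverlayEllipse = field(default_factory=OverlayEllipse)
    protocol_id: int = 0

    def __post_init__(self):
        if sorted(self.order) != list(range(1, len(self.order) + 1)):
            raise ConfigError("order must be a permutation of target ids")
        if self.time_limit_s <= 0:
            raise ConfigError("time limit must be positive")


@dataclass(frozen=True)
class SampleRecord:
    """One timestamped encoder+pedal sample."""

    t: float
    enc: EncoderReading
    pedal: bool


@dataclass(frozen=True)
class AcquisitionEvent:
    """Outcome of one target: pedal press or timeout."""

    target_id: int
    t_press: float
    accuracy_at_press: float
    roll_at_press: float
    timed_out: bool


@dataclass
class TrialLog:
    """Raw record of one trial: sample arrays plus acquisition events."""

    trial_index: int
    protocol: ExerciseProtocol
    t: np.ndarray             # (n,) seconds, strictly increasing
    theta: np.ndarray         # (n, 4) encoder radians (t1, t2, t3, t6)
    pedal: np.ndarray         # (n,) bool
    events: list[AcquisitionEvent]

    def iter_samples(self):
        for i in range(len(self.t)):
            yield SampleRecord(
                t=float(self.t[i]),
                enc=EncoderReading(*self.theta[i], t=float(self.t[i])),
                pedal=bool(self.pedal[i]),
            )

    @property
    def n_samples(self) -> int:
        return int(len(self.t))


@dataclass
class SessionLog:
    """One subject's session: a sequence of trials plus provenance."""

    subject_id: str
    seed: int
    config_fingerprint: str
    trials: list[TrialLog]


# --------------------------------------------------------------------------
# ideal focusing pose
# --------------------------------------------------------------------------

def _depth_for_shaft(c: np.ndarray, u: np.ndarray, optic_offset_deg: float):
    """Insertion depth putting the target on the optic cone for shaft u.

    With the tip on the shaft line through the fulcrum, the viewing angle
    to the target equals the optic offset exactly when
    ``d = c_par - c_perp / tan(offset)``; the viewing distance is then
    ``D = c_perp / sin(offset)``.
    """
    c_par = float(c @ u)
    c_perp = math.sqrt(max(0.0, float(c @ c) - c_par * c_par))
    off = math.radians(optic_offset_deg)
    d = c_par - c_perp / math.tan(off)
    D = c_perp / math.sin(off)
    return d, D


def ideal_focus_pose(target: TargetMarker, geom: ArmGeometry, cam: CameraModel,
                     overlay: OverlayEllipse, cavity: CavitySpec,
                     d_pref_list=(45.0, 30.0, 20.0, 12.0)) -> TipPose:
    """Numerically search a pose that focuses ``target`` head-on.

    The shaft direction is optimized so that the viewing distance is close
    to a preferred value and the view ray is as normal to the ring plane
    as possible, subject to the tip staying inside the cavity and distal
    to the fulcrum.  The roll is then pinned by requiring the optic cone
    to point at the ring centre.  Falls back to closer preferred distances
    until the overlay actually fits inside the projected ring.

    Raises
    ------
    ConfigError
        If no focusable pose is found for the target.
    """
    c = target.center
    off = geom.optic_offset_deg

    def build(a, b):
        u = shaft_from_angles(a, b)
        d, D = _depth_for_shaft(c, u, off)
        return u, d, D

    def objective(x, D_pref):
        u, d, D = build(x[0], x[1])
        tip = d * u
        cost = ((D - D_pref) / 20.0) ** 2
        v = c - tip
        vn = np.linalg.norm(v)
        if vn < 1e-9:
            return 1e6
        v = v / vn
        cos_inc = float(np.clip(v @ (-target.normal), -1.0, 1.0))
        inc = math.acos(cos_inc)            # 0 = face-on
        cost += 2.0 * inc ** 2
        plane_angle = math.degrees(math.asin(min(1.0, abs(float(v @ target.normal)))))
        if plane_angle < 12.0:
            cost += ((12.0 - plane_angle) / 5.0) ** 2 * 10.0
        if d < 1.0:
            cost += (1.0 - d) ** 2 * 10.0
        m = cavity.margin(tip)
        if m < 0.5:
            cost += (0.5 - m) ** 2 * 5.0
        return cost

    # start: look at the target from along its normal
    for D_pref in d_pref_list:
        tip0 = c + min(D_pref, max(5.0, float(np.linalg.norm(c)) - 2.0)) * target.normal
        if tip0[2] <= 1.0:
            tip0[2] = 1.0
        u0 = tip0 / np.linalg.norm(tip0)
        a0, b0 = angles_from_shaft(u0)
        res = minimize(objective, x0=[float(a0), float(b0)], args=(D_pref,),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400})
        u, d, D = build(res.x[0], res.x[1])
        if d < 0.0:
            continue
        tip = d * u
        v = (c - tip) / np.linalg.norm(c - tip)
        roll = roll_for_view(u, v, off)
        pose = pose_from_shaft(float(res.x[0]), float(res.x[1]), float(d), roll, geom)
        try:
            ring = project_ring(target, pose, cam)
        except (NotVisibleError, ObliqueDegenerateError):
            continue
        if is_focused(overlay, ring, cam):
            return pose
    raise ConfigError(f"no focusable pose found for target {target.id} "
                      f"({target.anatomical_label})")


# --------------------------------------------------------------------------
# exercise setup bundle
# --------------------------------------------------------------------------

@dataclass
class ExerciseSetup:
    """Everything a trial needs: geometry, camera, cavity, targets and the
    per-target ideal focusing poses (which define nominal rolls)."""

    geom: ArmGeometry
    cam: CameraModel
    cavity: CavitySpec
    targets: list[TargetMarker]
    overlay: OverlayEllipse
    home_q: tuple[float, float, float, float]   # (pan, tilt, depth, roll)
    ideal_poses: dict[int, TipPose]
    sample_dt: float = 0.02                      # 50 Hz

    def target_by_id(self, tid: int) -> TargetMarker:
        return self._by_id[tid]

    def __post_init__(self):
        self._by_id = {t.id: t for t in self.targets}

    @property
    def home_pose(self) -> TipPose:
        return pose_from_shaft(*self.home_q, geom=self.geom)

    def ideal_q(self, tid: int) -> np.ndarray:
        p = self.ideal_poses[tid]
        a, b = angles_from_shaft(p.shaft_dir)
        return np.array([float(a), float(b), p.insertion_depth, p.roll])


def make_setup(geom: ArmGeometry | None = None, cam: CameraModel | None = None,
               cavity: CavitySpec | None = None,
               overlay: OverlayEllipse | None = None,
               sample_dt: float = 0.02) -> ExerciseSetup:
    """Build the default exercise setup and solve the ideal poses."""
    geom = geom or default_geometry()
    cam = cam or CameraModel(optic_offset_deg=geom.optic_offset_deg)
    cavity = cavity or CavitySpec()
    overlay = overlay or OverlayEllipse()
    raw_targets = make_target_layout(cavity)
    targets = []
    ideal = {}
    for tg in raw_targets:
        pose = ideal_focus_pose(tg, geom, cam, overlay, cavity)
        tg = replace(tg, nominal_roll=float(pose.roll))
        ideal[tg.id] = pose
        targets.append(tg)
    return ExerciseSetup(geom=geom, cam=cam, cavity=cavity, targets=targets,
                         overlay=overlay, home_q=(0.0, 0.0, 5.0, 0.0),
                         ideal_poses=ideal, sample_dt=sample_dt)


# --------------------------------------------------------------------------
# trial engine
# --------------------------------------------------------------------------

def _event_accuracy(theta_row: np.ndarray, target: TargetMarker,
                    setup: ExerciseSetup):
    """Exact accuracy and roll for a logged sample (polygon clipping)."""
    enc = EncoderReading(*theta_row)
    pose, _ = resolve_tip_pose(enc, setup.geom)
    try:
        ring = project_ring(target, pose, setup.cam)
        acc = accuracy_score(setup.overlay, ring, setup.cam)
    except (NotVisibleError, ObliqueDegenerateError):
        acc = 0.0
    return acc, pose.roll


def run_trial(agent, protocol: ExerciseProtocol, setup: ExerciseSetup,
              rng: np.random.Generator, trial_index: int = 1) -> TrialLog:
    """Execute one trial of the navigation exercise.

    The ``agent`` must implement
    ``play_target(q_start, target, setup, protocol, trial_index, rng)``
    returning ``(times, qs, press_index)`` where ``times`` is a strictly
    increasing array of seconds (starting after 0), ``qs`` the matching
    ``(n, 4)`` array of shaft-space samples (pan, tilt rad; depth mm;
    roll deg), and ``press_index`` the sample of the pedal press or
    ``None``.  Samples past the per-target window are discarded; a press
    outside the window becomes a timeout with zero accuracy.
    """
    limit = protocol.time_limit_s
    q_cur = np.asarray(setup.home_q, float)
    t_chunks = [np.array([0.0])]
    q_chunks = [q_cur[None, :]]
    pedal_chunks = [np.array([False])]
    events: list[AcquisitionEvent] = []
    t0 = 0.0

    for tid in protocol.order:
        target = setup.target_by_id(tid)
        times, qs, press_idx = agent.play_target(q_cur, target, setup,
                                                 protocol, trial_index, rng)
        times = np.asarray(times, float)
        qs = np.asarray(qs, float)
        if times.size == 0:
            raise AgentStallError(f"agent emitted no samples for target {tid}")
        gaps = np.diff(np.concatenate([[0.0], times]))
        if np.any(gaps <= 0.0):
            raise AgentStallError("sample times not strictly increasing")
        if np.any(gaps > 1.0 + 1e-9):
            raise AgentStallError("agent silent for > 1 s of simulated time")

        timed_out = press_idx is None or times[press_idx] > limit
        if timed_out:
            keep = times <= limit
            t_evt = t0 + limit
        else:
            keep = np.arange(len(times)) <= press_idx
            t_evt = t0 + float(times[press_idx])
        times_k, qs_k = times[keep], qs[keep]
        if times_k.size == 0:   # window shorter than first sample
            times_k = np.array([limit])
            qs_k = q_cur[None, :]
        pedal_k = np.zeros(len(times_k), dtype=bool)
        if not timed_out:
            pedal_k[-1] = True

        theta_last = encoders_from_shaft_batch(
            qs_k[-1, 0], qs_k[-1, 1], qs_k[-1, 2], qs_k[-1, 3], setup.geom)[0]
        if timed_out:
            acc = 0.0
            _, roll_evt = _event_accuracy(theta_last, target, setup)
        else:
            acc, roll_evt = _event_accuracy(theta_last, target, setup)

        t_chunks.append(t0 + times_k)
        q_chunks.append(qs_k)
        pedal_chunks.append(pedal_k)
        events.append(AcquisitionEvent(target_id=tid, t_press=t_evt,
                                       accuracy_at_press=float(acc),
                                       roll_at_press=float(roll_evt),
                                       timed_out=bool(timed_out)))
        q_cur = qs_k[-1].copy()
        t0 = t_evt

    t_all = np.concatenate(t_chunks)
    q_all = np.concatenate(q_chunks, axis=0)
    pedal_all = np.concatenate(pedal_chunks)
    # de-duplicate identical consecutive timestamps from event boundaries
    keep = np.concatenate([[True], np.diff(t_all) > 1e-12])
    t_all, q_all, pedal_all = t_all[keep], q_all[keep], pedal_all[keep]
    theta = encoders_from_shaft_batch(q_all[:, 0], q_all[:, 1], q_all[:, 2],
                                      q_all[:, 3], setup.geom)
    return TrialLog(trial_index=trial_index, protocol=protocol, t=t_all,
                    theta=theta, pedal=pedal_all, events=events)
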