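"""Remote-center-of-motion kinematics of a passive 6-joint tracker arm.

A rigid endoscope enters the anatomical cavity through a fixed fulcrum
point ``F`` (the natural-orifice entrance).  The scope is carried by a
passive arm with six rotational joints, of which only four carry encoders
(theta1, theta2, theta3 on the positioning chain, theta6 for shaft roll).
Because the shaft is constrained to pass through ``F``, the two unencoded
gimbal joints (theta4, theta5) are fully determined: the shaft axis is the
line through the chain's attachment point ``A`` and ``F``, so four encoder
readings suffice to recover the complete tip pose.

Conventions
-----------
* Cavity frame: right-handed, origin at the fulcrum ``F``, ``+z`` into the
  cavity along the mean insertion axis, ``+y`` superior.
* Positions in mm.  Angles are radians in :class:`EncoderReading` and
  :class:`FullJointState` (raw joint space) and degrees at the pose-level
  API surface (``roll``).
* Positioning chain (yaw-pitch-pitch)::

      T(theta) = T_base . Rz(t1) . Tx(l1) . Ry(t2) . Tx(l2) . Ry(t3) . Tx(l3)

  so the all-zero configuration puts the attachment point at
  ``base + (l1+l2+l3) * x_base``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateAxisError, RetractedToolError, UnreachableError

__all__ = [
    "ArmGeometry",
    "EncoderReading",
    "FullJointState",
    "TipPose",
    "default_geometry",
    "chain_attachment_point",
    "resolve_tip_pose",
    "encoders_from_pose",
    "view_direction",
    "roll_for_view",
    "shaft_from_angles",
    "angles_from_shaft",
    "pose_from_shaft",
    "shaft_coords",
    "wrap_angle",
    "wrap_deg",
]

_EPS_AXIS_MM = 1e-6


def wrap_angle(theta):
    """Wrap radians to the half-open interval (-pi, pi]."""
    t = np.asarray(theta, dtype=float)
    w = -((-t + np.pi) % (2.0 * np.pi) - np.pi)
    return w if w.ndim else float(w)


def wrap_deg(angle):
    """Wrap degrees to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    w = -((-a + 180.0) % 360.0 - 180.0)
    return w if w.ndim else float(w)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class ArmGeometry:
    """Physical constants of the tracker arm and scope.

    Parameters
    ----------
    base_position : (3,) array
        Arm base origin in the cavity frame (mm).
    base_rotation : (3, 3) array
        Columns are the base frame axes expressed in the cavity frame.
    link_lengths : (l1, l2, l3)
        Lengths of the three positioning links (mm).
    tool_length : float
        Distance from the attachment point to the scope tip (mm).
    rcm_point : (3,) array
        Fulcrum ``F`` in the cavity frame (mm); the origin by convention.
    optic_offset_deg : float
        Tilt of the optical axis from the shaft axis (30 for the oblique
        scope used in the navigation exercise).
    joint_signs : (6,) ints
        Per-joint sign convention (+1/-1).
    """

    base_position: np.ndarray
    base_rotation: np.ndarray
    link_lengths: tuple[float, float, float]
    tool_length: float
    rcm_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    optic_offset_deg: float = 30.0
    joint_signs: tuple[int, ...] = (1, 1, 1, 1, 1, 1)

    def __post_init__(self):
        object.__setattr__(self, "base_position", np.asarray(self.base_position, float))
        object.__setattr__(self, "base_rotation", np.asarray(self.base_rotation, float))
        object.__setattr__(self, "rcm_point", np.asarray(self.rcm_point, float))
        if any(l <= 0 for l in self.link_lengths) or self.tool_length <= 0:
            raise ValueError("link lengths and tool length must be positive")
        R = self.base_rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("base_rotation must be orthonormal")
        reach = sum(self.link_lengths) + self.tool_length
        if np.linalg.norm(self.rcm_point - self.base_position) >= reach:
            raise ValueError("fulcrum outside the arm's reach")

    @property
    def total_link_length(self) -> float:
        return float(sum(self.link_lengths))


def default_geometry(optic_offset_deg: float = 30.0) -> ArmGeometry:
    """Reference arm geometry.

    The base sits ~300 mm from the fulcrum, above and behind it, with the
    home axis pointing at the region swept by the attachment point during
    normal operation (attachment 290-350 mm behind ``F`` inside a ~40 deg
    cone).  Link lengths 150/200/200 mm, tool length 350 mm.
    """
    base = np.array([0.0, 260.0, -150.0])
    x_axis = _unit(np.array([0.0, -260.0, -150.0]))  # toward the working region
    y_axis = np.array([1.0, 0.0, 0.0])
    z_axis = np.cross(x_axis, y_axis)
    R = np.column_stack([x_axis, y_axis, z_axis])
    return ArmGeometry(
        base_position=base,
        base_rotation=R,
        link_lengths=(150.0, 200.0, 200.0),
        tool_length=350.0,
        optic_offset_deg=optic_offset_deg,
    )


@dataclass(frozen=True)
class EncoderReading:
    """One reading of the four encoded joints, radians, wrapped to (-pi, pi]."""

    theta1: float
    theta2: float
    theta3: float
    theta6: float
    t: float = 0.0

    def __post_init__(self):
        for name in ("theta1", "theta2", "theta3", "theta6"):
            object.__setattr__(self, name, wrap_angle(getattr(self, name)))
        if self.t < 0:
            raise ValueError("timestamp must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3, self.theta6])


@dataclass(frozen=True)
class FullJointState:
    """All six joint angles (radians); theta4/theta5 are reconstructed."""

    theta1: float
    theta2: float
    theta3: float
    theta4: float
    theta5: float
    theta6: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3,
                         self.theta4, self.theta5, self.theta6])


@dataclass(frozen=True)
class TipPose:
    """Endoscope tip pose in the cavity frame.

    ``position = F + insertion_depth * shaft_dir`` and the view axis makes
    the optic-offset angle with the shaft axis.
    """

    position: np.ndarray
    shaft_dir: np.ndarray
    view_dir: np.ndarray
    roll: float  # degrees
    insertion_depth: float  # mm, along the shaft from F

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, float))
        object.__setattr__(self, "shaft_dir", np.asarray(self.shaft_dir, float))
        object.__setattr__(self, "view_dir", np.asarray(self.view_dir, float))


# --------------------------------------------------------------------------
# forward chain
# --------------------------------------------------------------------------

def chain_attachment_point(enc3, geom: ArmGeometry):
    """Forward kinematics of the encoded 3R positioning chain.

    Parameters
    ----------
    enc3 : (theta1, theta2, theta3) in radians, scalars or arrays.
    geom : ArmGeometry

    Returns
    -------
    (3,) or (n, 3) array: attachment point(s) A in the cavity frame (mm).
    """
    t1 = np.asarray(enc3[0], float) * geom.joint_signs[0]
    t2 = np.asarray(enc3[1], float) * geom.joint_signs[1]
    t3 = np.asarray(enc3[2], float) * geom.joint_signs[2]
    l1, l2, l3 = geom.link_lengths
    c1, s1 = np.cos(t1), np.sin(t1)
    c2, s2 = np.cos(t2), np.sin(t2)
    c23, s23 = np.cos(t2 + t3), np.sin(t2 + t3)
    # planar (x, z) coordinates in the yaw plane; Ry(t) x_hat = (cos t, 0, -sin t)
    r = l1 + l2 * c2 + l3 * c23
    z = -(l2 * s2 + l3 * s23)
    p_base = np.stack([r * c1, r * s1, z], axis=-1)
    return geom.base_position + p_base @ geom.base_rotation.T


def _distal_rotation(t1, t2, t3, geom: ArmGeometry) -> np.ndarray:
    """Orientation of the chain frame after joint 3 (scalar angles)."""
    s = geom.joint_signs

    def Rz(a):
        c, si = math.cos(a), math.sin(a)
        return np.array([[c, -si, 0.0], [si, c, 0.0], [0.0, 0.0, 1.0]])

    def Ry(a):
        c, si = math.cos(a), math.sin(a)
        return np.array([[c, 0.0, si], [0.0, 1.0, 0.0], [-si, 0.0, c]])

    return geom.base_rotation @ Rz(t1 * s[0]) @ Ry(t2 * s[1]) @ Ry(t3 * s[2])


# --------------------------------------------------------------------------
# oblique optic
# --------------------------------------------------------------------------

def _roll_basis(shaft_dir: np.ndarray):
    """Gravity-referenced basis (e1, e2) orthogonal to the shaft.

    e1 is the superior direction projected off the shaft (image horizon is
    held fixed by the optical coupler); falls back to +x when the shaft is
    aligned with gravity.
    """
    u = np.asarray(shaft_dir, float)
    ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ u) * u
    n = np.linalg.norm(e1)
    if n < 1e-8:
        ref = np.array([1.0, 0.0, 0.0])
        e1 = ref - (ref @ u) * u
        n = np.linalg.norm(e1)
    e1 = e1 / n
    e2 = np.cross(u, e1)
    return e1, e2


def view_direction(shaft_dir, roll_deg: float, optic_offset_deg: float) -> np.ndarray:
    """Optical axis of an oblique scope.

    The view axis is tilted ``optic_offset_deg`` away from the shaft axis
    and swung about it by ``roll_deg``.  Positive roll is clockwise as seen
    looking down the shaft from the eyepiece (i.e. along ``+shaft_dir``).
    """
    u = _unit(np.asarray(shaft_dir, float))
    off = math.radians(optic_offset_deg)
    if off == 0.0:
        return u.copy()
    e1, e2 = _roll_basis(u)
    r = math.radians(roll_deg)
    w = math.cos(r) * e1 - math.sin(r) * e2
    return math.cos(off) * u + math.sin(off) * w


def roll_for_view(shaft_dir, target_view, optic_offset_deg: float) -> float:
    """Roll (degrees) that points the optic cone toward ``target_view``.

    ``target_view`` need not lie exactly on the cone; its component
    orthogonal to the shaft selects the roll.
    """
    u = _unit(np.asarray(shaft_dir, float))
    v = np.asarray(target_view, float)
    w = v - (v @ u) * u
    n = np.linalg.norm(w)
    if n < 1e-12:
        return 0.0
    w = w / n
    e1, e2 = _roll_basis(u)
    return math.degrees(math.atan2(-(w @ e2), w @ e1))


# --------------------------------------------------------------------------
# shaft-space parametrization (pan a, tilt b, depth d, roll)
# --------------------------------------------------------------------------

def shaft_from_angles(a, b):
    """Shaft direction from pan ``a`` (about +y) and tilt ``b`` (about +x),
    radians: u = Ry(a) Rx(b) z_hat."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return np.stack([np.sin(a) * np.cos(b), -np.sin(b), np.cos(a) * np.cos(b)],
                    axis=-1)


def angles_from_shaft(u):
    """Inverse of :func:`shaft_from_angles`."""
    u = np.asarray(u, float)
    b = -np.arcsin(np.clip(u[..., 1], -1.0, 1.0))
    a = np.arctan2(u[..., 0], u[..., 2])
    return a, b


def pose_from_shaft(a: float, b: float, d: float, roll_deg: float,
                    geom: ArmGeometry) -> TipPose:
    """Tip pose from shaft-space coordinates (pan, tilt, depth, roll)."""
    u = shaft_from_angles(a, b)
    pos = geom.rcm_point + d * u
    view = view_direction(u, roll_deg, geom.optic_offset_deg)
    return TipPose(position=pos, shaft_dir=u, view_dir=view,
                   roll=float(roll_deg), insertion_depth=float(d))


def shaft_coords(pose: TipPose) -> tuple[float, float, float, float]:
    """(pan, tilt, depth, roll) coordinates of a pose."""
    a, b = angles_from_shaft(pose.shaft_dir)
    return float(a), float(b), float(pose.insertion_depth), float(pose.roll)


# --------------------------------------------------------------------------
# pose recovery from encoders
# --------------------------------------------------------------------------

def resolve_tip_pose(enc: EncoderReading, geom: ArmGeometry):
    """Recover the full tip pose from the four encoder readings.

    The shaft axis is the line through the attachment point ``A`` and the
    fulcrum ``F``; the tip lies at ``A + L*u`` with ``u = (F-A)/|F-A|``.
    The unencoded gimbal angles theta4/theta5 are the branch with
    ``|theta4| <= 90 deg`` aligning the distal chain frame with ``u``.

    Returns
    -------
    (TipPose, FullJointState)

    Raises
    ------
    DegenerateAxisError
        If the attachment point coincides with the fulcrum.
    RetractedToolError
        If the tip would lie proximal to the fulcrum (d < 0).
    """
    A = chain_attachment_point((enc.theta1, enc.theta2, enc.theta3), geom)
    m = geom.rcm_point - A
    dist = float(np.linalg.norm(m))
    if dist < _EPS_AXIS_MM:
        raise DegenerateAxisError("attachment point at the fulcrum")
    u = m / dist
    d = geom.tool_length - dist
    if d < -1e-9:
        raise RetractedToolError(d)
    d = max(d, 0.0)
    pos = A + geom.tool_length * u

    Rd = _distal_rotation(enc.theta1, enc.theta2, enc.theta3, geom)
    v = Rd.T @ u  # shaft direction in the distal chain frame
    t4 = math.atan2(v[1], v[0])
    t5 = -math.asin(np.clip(v[2], -1.0, 1.0))
    if abs(t4) > math.pi / 2.0:  # pick the |theta4| <= 90 deg branch
        t4 = wrap_angle(t4 + math.pi)
        t5 = wrap_angle(math.pi - t5)
    roll = math.degrees(enc.theta6 * geom.joint_signs[5])
    view = view_direction(u, roll, geom.optic_offset_deg)
    pose = TipPose(position=pos, shaft_dir=u, view_dir=view, roll=roll,
                   insertion_depth=d)
    state = FullJointState(enc.theta1, enc.theta2, enc.theta3, t4, t5, enc.theta6)
    return pose, state


def resolve_tip_batch(theta: np.ndarray, geom: ArmGeometry):
    """Vectorized pose recovery for metric computation.

    Parameters
    ----------
    theta : (n, 4) array of (theta1, theta2, theta3, theta6) radians.

    Returns
    -------
    tips : (n, 3) tip positions (mm)
    rolls : (n,) roll angles (degrees)
    depths : (n,) insertion depths (mm)
    """
    theta = np.asarray(theta, float)
    A = chain_attachment_point((theta[:, 0], theta[:, 1], theta[:, 2]), geom)
    m = geom.rcm_point[None, :] - A
    dist = np.linalg.norm(m, axis=1)
    if np.any(dist < _EPS_AXIS_MM):
        raise DegenerateAxisError("attachment point at the fulcrum")
    u = m / dist[:, None]
    tips = A + geom.tool_length * u
    rolls = np.degrees(theta[:, 3] * geom.joint_signs[5])
    depths = geom.tool_length - dist
    return tips, rolls, depths


# --------------------------------------------------------------------------
# inverse: encoders from a desired pose
# --------------------------------------------------------------------------

def _ik_chain(A: np.ndarray, geom: ArmGeometry):
    """Closed-form 3R inverse kinematics to place the attachment at ``A``.

    Deterministic branch: positive-elbow (theta3 = +acos), yaw from atan2.
    """
    l1, l2, l3 = geom.link_lengths
    w = geom.base_rotation.T @ (np.asarray(A, float) - geom.base_position)
    r = math.hypot(w[0], w[1])
    t1 = math.atan2(w[1], w[0]) if r > 1e-12 else 0.0
    X = r - l1
    Z = -w[2]
    rho2 = X * X + Z * Z
    c3 = (rho2 - l2 * l2 - l3 * l3) / (2.0 * l2 * l3)
    if c3 > 1.0 + 1e-9 or c3 < -1.0 - 1e-9:
        raise UnreachableError(f"attachment point outside 3R workspace (cos t3 = {c3:.4f})")
    c3 = float(np.clip(c3, -1.0, 1.0))
    t3 = math.acos(c3)
    t2 = math.atan2(Z, X) - math.atan2(l3 * math.sin(t3), l2 + l3 * c3)
    s = geom.joint_signs
    return wrap_angle(t1 / s[0]), wrap_angle(t2 / s[1]), wrap_angle(t3 / s[2])


def encoders_from_pose(pose: TipPose, geom: ArmGeometry, t: float = 0.0) -> EncoderReading:
    """Encoder readings that reproduce ``pose`` under :func:`resolve_tip_pose`.

    The attachment point is ``position - L*shaft_dir``; the 3R chain is
    solved in closed form with a deterministic branch choice.

    Raises
    ------
    UnreachableError
        If the required attachment point is outside the 3R workspace.
    """
    A = pose.position - geom.tool_length * np.asarray(pose.shaft_dir, float)
    t1, t2, t3 = _ik_chain(A, geom)
    t6 = wrap_angle(math.radians(pose.roll) / geom.joint_signs[5])
    return EncoderReading(t1, t2, t3, t6, t=t)


def encoders_from_shaft_batch(a, b, d, roll_deg, geom: ArmGeometry) -> np.ndarray:
    """Vectorized inverse kinematics from shaft-space trajectories.

    Parameters are broadcastable arrays (pan, tilt rad; depth mm; roll deg).

    Returns
    -------
    (n, 4) array of (theta1, theta2, theta3, theta6) radians.
    """
    a = np.atleast_1d(np.asarray(a, float))
    b = np.atleast_1d(np.asarray(b, float))
    d = np.atleast_1d(np.asarray(d, float))
    roll = np.atleast_1d(np.asarray(roll_deg, float))
    u = shaft_from_angles(a, b)
    A = geom.rcm_point[None, :] + (d[:, None] - geom.tool_length) * u
    l1, l2, l3 = geom.link_lengths
    w = (A - geom.base_position[None, :]) @ geom.base_rotation
    r = np.hypot(w[:, 0], w[:, 1])
    t1 = np.where(r > 1e-12, np.arctan2(w[:, 1], w[:, 0]), 0.0)
    X = r - l1
    Z = -w[:, 2]
    c3 = (X * X + Z * Z - l2 * l2 - l3 * l3) / (2.0 * l2 * l3)
    if np.any(c3 > 1.0 + 1e-9) or np.any(c3 < -1.0 - 1e-9):
        raise UnreachableError("trajectory leaves the 3R workspace")
    c3 = np.clip(c3, -1.0, 1.0)
    t3 = np.arccos(c3)
    t2 = np.arctan2(Z, X) - np.arctan2(l3 * np.sin(t3), l2 + l3 * c3)
    s = geom.joint_signs
    out = np.stack([
        wrap_angle(t1 / s[0]),
        wrap_angle(t2 / s[1]),
        wrap_angle(t3 / s[2]),
        wrap_angle(np.radians(roll) / s[5]),
    ], axis=1)
    return out
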