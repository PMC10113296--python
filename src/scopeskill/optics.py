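"""Oblique-optic camera model, ring-target projection and focus scoring.

The navigation exercise asks the trainee to centre an on-screen ellipse
(a fixed reticle at the principal point) inside the black ring that
surrounds each LED target.  Accuracy at the pedal press is the percentage
of the ellipse area lying inside the projected ring.

The camera is an ideal pinhole looking along the scope's view axis; the
optical coupler keeps the image horizon gravity-aligned while the optic
cone swings with shaft roll, so the camera up-vector is derived from the
world +y axis, not from the roll angle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon

from .errors import (
    BehindCameraError,
    NotVisibleError,
    ObliqueDegenerateError,
)
from .kinematics import TipPose

__all__ = [
    "CameraModel",
    "TargetMarker",
    "OverlayEllipse",
    "ProjectedRing",
    "camera_basis",
    "project_point",
    "project_points",
    "project_ring",
    "accuracy_score",
    "is_focused",
    "focus_score_fast",
    "ellipse_polygon",
]

_VIS_CONE_DEG = 60.0   # half-angle of the visibility cone
_GRAZE_DEG = 5.0       # minimum angle between view ray and ring plane


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera on the oblique optic."""

    fov_deg: float = 70.0                 # horizontal field of view
    image_size: tuple[int, int] = (640, 480)
    principal_point: tuple[float, float] | None = None
    optic_offset_deg: float = 30.0
    near_limit_mm: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.fov_deg < 180.0):
            raise ValueError("fov must be in (0, 180)")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image size must be positive")
        if not (0.0 <= self.optic_offset_deg < 90.0):
            raise ValueError("optic offset must be in [0, 90)")
        if self.principal_point is None:
            object.__setattr__(self, "principal_point",
                               (self.image_size[0] / 2.0, self.image_size[1] / 2.0))

    @property
    def focal_px(self) -> float:
        return (self.image_size[0] / 2.0) / math.tan(math.radians(self.fov_deg) / 2.0)


@dataclass(frozen=True)
class TargetMarker:
    """One wall target: a white LED inside a black annulus."""

    id: int
    center: np.ndarray                  # mm, cavity frame
    normal: np.ndarray                  # unit, pointing into the cavity
    ring_outer_radius: float = 6.0      # mm
    ring_inner_radius: float = 4.0
    led_radius: float = 2.0
    nominal_roll: float = 0.0           # degrees, pre-defined scope orientation
    anatomical_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float))
        n = np.asarray(self.normal, float)
        object.__setattr__(self, "normal", n / np.linalg.norm(n))
        if not (0.0 < self.led_radius < self.ring_inner_radius < self.ring_outer_radius):
            raise ValueError("need 0 < led < inner < outer radius")


@dataclass(frozen=True)
class OverlayEllipse:
    """The on-screen reticle; fixed at the principal point."""

    semi_major: float = 40.0    # px
    semi_minor: float = 28.0
    orientation_deg: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.semi_minor <= self.semi_major):
            raise ValueError("need 0 < semi_minor <= semi_major")


@dataclass(frozen=True)
class ProjectedRing:
    """Image-space polygonal approximation of a projected ring target."""

    outer_boundary: np.ndarray   # (n, 2) px
    inner_boundary: np.ndarray
    visible: bool = True

    def __post_init__(self):
        object.__setattr__(self, "outer_boundary", np.asarray(self.outer_boundary, float))
        object.__setattr__(self, "inner_boundary", np.asarray(self.inner_boundary, float))


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------

def camera_basis(pose: TipPose) -> np.ndarray:
    """Rows (x_cam, y_cam, z_cam): right, up, forward in the cavity frame."""
    z = np.asarray(pose.view_dir, float)
    z = z / np.linalg.norm(z)
    up = np.array([0.0, 1.0, 0.0])
    x = np.cross(up, z)
    n = np.linalg.norm(x)
    if n < 1e-8:                      # looking along gravity: fall back
        up = np.array([0.0, 0.0, 1.0])
        x = np.cross(up, z)
        n = np.linalg.norm(x)
    x = x / n
    y = np.cross(z, x)
    return np.stack([x, y, z])


def project_points(pts: np.ndarray, pose: TipPose, cam: CameraModel):
    """Vectorized pinhole projection.

    Returns
    -------
    px : (n, 2) pixel coordinates (pixel y grows downward)
    depth : (n,) depths along the view axis (mm)
    """
    B = camera_basis(pose)
    rel = (np.atleast_2d(pts) - pose.position) @ B.T
    depth = rel[:, 2]
    f = cam.focal_px
    cx, cy = cam.principal_point
    with np.errstate(divide="ignore", invalid="ignore"):
        u = cx + f * rel[:, 0] / depth
        v = cy - f * rel[:, 1] / depth
    return np.stack([u, v], axis=1), depth


def project_point(p, pose: TipPose, cam: CameraModel) -> np.ndarray:
    """Project a single point; raises :class:`BehindCameraError` if the
    point is on or behind the near plane."""
    px, depth = project_points(np.asarray(p, float)[None, :], pose, cam)
    if depth[0] <= cam.near_limit_mm:
        raise BehindCameraError(f"depth {depth[0]:.3f} mm <= near limit")
    return px[0]


def _circle_points_3d(center, normal, radius, n):
    normal = np.asarray(normal, float)
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(normal, a)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return (np.asarray(center, float)[None, :]
            + radius * (np.cos(ang)[:, None] * t1 + np.sin(ang)[:, None] * t2))


def project_ring(target: TargetMarker, pose: TipPose, cam: CameraModel,
                 n_vertices: int = 128) -> ProjectedRing:
    """Project a ring target into the image.

    Raises
    ------
    NotVisibleError
        If any boundary sample is behind the camera or outside the
        120-degree visibility cone.
    ObliqueDegenerateError
        If the view ray meets the ring plane at < 5 degrees (grazing).
    """
    view = np.asarray(pose.view_dir, float)
    ray = target.center - pose.position
    rn = np.linalg.norm(ray)
    if rn < 1e-9:
        raise NotVisibleError("camera at the target centre")
    ray = ray / rn
    plane_angle = 90.0 - math.degrees(
        math.acos(np.clip(abs(ray @ target.normal), -1.0, 1.0)))
    if plane_angle < _GRAZE_DEG:
        raise ObliqueDegenerateError(f"grazing incidence ({plane_angle:.2f} deg)")

    boundaries = []
    for radius in (target.ring_outer_radius, target.ring_inner_radius):
        pts3 = _circle_points_3d(target.center, target.normal, radius, n_vertices)
        px, depth = project_points(pts3, pose, cam)
        if np.any(depth <= cam.near_limit_mm):
            raise NotVisibleError("ring boundary behind the camera")
        rel = pts3 - pose.position
        cosang = (rel @ view) / np.linalg.norm(rel, axis=1)
        if np.any(cosang < math.cos(math.radians(_VIS_CONE_DEG))):
            raise NotVisibleError("ring boundary outside the visibility cone")
        boundaries.append(px)
    return ProjectedRing(outer_boundary=boundaries[0], inner_boundary=boundaries[1],
                         visible=True)


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def ellipse_polygon(overlay: OverlayEllipse, center: tuple[float, float],
                    n_vertices: int = 128) -> np.ndarray:
    """(n, 2) polygonal approximation of the overlay ellipse."""
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    x = overlay.semi_major * np.cos(ang)
    y = overlay.semi_minor * np.sin(ang)
    phi = math.radians(overlay.orientation_deg)
    c, s = math.cos(phi), math.sin(phi)
    return np.stack([center[0] + c * x - s * y,
                     center[1] + s * x + c * y], axis=1)


def accuracy_score(overlay: OverlayEllipse, ring: ProjectedRing,
                   cam: CameraModel, boundary: str = "outer") -> float:
    """Percentage of the overlay ellipse inside the ring (polygon clipping).

    ``boundary`` selects which ring boundary delimits the valid zone;
    the black circle's outer edge by default.
    """
    if not ring.visible:
        raise NotVisibleError("ring not visible")
    ell = Polygon(ellipse_polygon(overlay, cam.principal_point))
    zone = Polygon(ring.outer_boundary if boundary == "outer" else ring.inner_boundary)
    if not zone.is_valid:
        zone = zone.buffer(0)
    inter = ell.intersection(zone).area
    score = 100.0 * inter / ell.area
    return float(min(100.0, max(0.0, score)))


def is_focused(overlay: OverlayEllipse, ring: ProjectedRing, cam: CameraModel,
               boundary: str = "outer", tol: float = 1e-9) -> bool:
    """True iff the overlay lies entirely inside the ring (score = 100)."""
    return accuracy_score(overlay, ring, cam, boundary) >= 100.0 - tol


# --------------------------------------------------------------------------
# fast perceptual proxy (used by the synthetic surgeon at ~10 Hz)
# --------------------------------------------------------------------------

def _sunflower_disc(n: int) -> np.ndarray:
    """Deterministic equal-area-ish point layout on the unit disc."""
    k = np.arange(1, n + 1)
    r = np.sqrt((k - 0.5) / n)
    th = k * (np.pi * (3.0 - np.sqrt(5.0)))
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)

_PROXY_DISC = _sunflower_disc(48)


def focus_score_fast(pose: TipPose, target: TargetMarker, cam: CameraModel,
                     overlay: OverlayEllipse, n_ring: int = 64,
                     boundary: str = "outer") -> float:
    """Cheap approximate accuracy score (sampled containment, 0..100).

    Projects the ring boundary with ``n_ring`` vertices and counts which of
    48 deterministic overlay sample points fall inside.  Returns 0 when the
    ring is not visible.  Used for the agent's perceived score; the exact
    polygon-clipped :func:`accuracy_score` is always used for logged events.
    """
    try:
        ring = project_ring(target, pose, cam, n_vertices=n_ring)
    except (NotVisibleError, ObliqueDegenerateError):
        return 0.0
    bnd = ring.outer_boundary if boundary == "outer" else ring.inner_boundary
    cx, cy = cam.principal_point
    phi = math.radians(overlay.orientation_deg)
    c, s = math.cos(phi), math.sin(phi)
    x = overlay.semi_major * _PROXY_DISC[:, 0]
    y = overlay.semi_minor * _PROXY_DISC[:, 1]
    pts = np.stack([cx + c * x - s * y, cy + s * x + c * y], axis=1)
    inside = MplPath(bnd).contains_points(pts)
    return 100.0 * float(np.count_nonzero(inside)) / len(pts)
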