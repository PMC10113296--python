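"""Pinhole projection of ring targets and ellipse-in-ring scoring."""

import math

import numpy as np
import pytest
from matplotlib.path import Path as MplPath

from scopeskill.errors import BehindCameraError, NotVisibleError, ObliqueDegenerateError
from scopeskill.kinematics import default_geometry, pose_from_shaft
from scopeskill.optics import (
    CameraModel,
    OverlayEllipse,
    ProjectedRing,
    TargetMarker,
    accuracy_score,
    ellipse_polygon,
    focus_score_fast,
    is_focused,
    project_point,
    project_ring,
)

GEOM = default_geometry()
CAM = CameraModel()


def straight_pose(d=10.0, roll=0.0):
    """Pose with known view axis (30 deg optic, shaft along +z)."""
    return pose_from_shaft(0.0, 0.0, d, roll, GEOM)


def circle_ring(radius_px, center, n=128):
    """Synthetic image-space ring with circular boundaries."""
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    outer = np.stack([center[0] + radius_px * np.cos(ang),
                      center[1] + radius_px * np.sin(ang)], axis=1)
    inner = outer * 0.6 + np.asarray(center) * 0.4
    return ProjectedRing(outer_boundary=outer, inner_boundary=inner)


def rasterized_score(overlay, ring, cam, n_samples=200_000, seed=0):
    """Independent Monte-Carlo oracle: fraction of random points of the
    overlay ellipse that fall inside the ring's outer polygon."""
    rng = np.random.default_rng(seed)
    r = np.sqrt(rng.uniform(0, 1, n_samples))
    th = rng.uniform(0, 2 * np.pi, n_samples)
    x = overlay.semi_major * r * np.cos(th)
    y = overlay.semi_minor * r * np.sin(th)
    phi = math.radians(overlay.orientation_deg)
    c, s = math.cos(phi), math.sin(phi)
    cx, cy = cam.principal_point
    pts = np.stack([cx + c * x - s * y, cy + s * x + c * y], axis=1)
    inside = MplPath(ring.outer_boundary).contains_points(pts)
    return 100.0 * inside.mean()


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------

def test_point_on_axis_hits_principal_point():
    pose = straight_pose()
    p = pose.position + 50.0 * pose.view_dir
    px = project_point(p, pose, CAM)
    assert np.allclose(px, CAM.principal_point, atol=1e-9)


def test_point_behind_camera_raises():
    pose = straight_pose()
    with pytest.raises(BehindCameraError):
        project_point(pose.position - 10.0 * pose.view_dir, pose, CAM)


def test_projection_matrix_oracle(rng):
    """project_point matches an explicit homogeneous projection matrix."""
    from scopeskill.optics import camera_basis

    pose = pose_from_shaft(0.2, -0.15, 25.0, 40.0, GEOM)
    B = camera_basis(pose)
    f = CAM.focal_px
    cx, cy = CAM.principal_point
    K = np.array([[f, 0, cx], [0, -f, cy], [0, 0, 1.0]])
    P = K @ np.hstack([B, -(B @ pose.position)[:, None]])  # 3x4
    for _ in range(20):
        p = pose.position + pose.view_dir * rng.uniform(5, 80) \
            + rng.normal(0, 5, 3)
        h = P @ np.append(p, 1.0)
        if h[2] <= CAM.near_limit_mm:
            continue
        assert np.allclose(project_point(p, pose, CAM), h[:2] / h[2], atol=1e-6)


def test_face_on_ring_projects_to_circle_of_pinhole_radius():
    """A face-on centred ring of radius r at distance D projects to a
    circle of radius f*r/D pixels."""
    pose = straight_pose()
    D = 40.0
    center = pose.position + D * pose.view_dir
    tgt = TargetMarker(id=1, center=center, normal=-pose.view_dir)
    ring = project_ring(tgt, pose, CAM)
    radii = np.linalg.norm(ring.outer_boundary - np.array(CAM.principal_point), axis=1)
    expected = CAM.focal_px * tgt.ring_outer_radius / D
    assert np.allclose(radii, expected, rtol=1e-9)
    inner = np.linalg.norm(ring.inner_boundary - np.array(CAM.principal_point), axis=1)
    assert np.allclose(inner, CAM.focal_px * tgt.ring_inner_radius / D, rtol=1e-9)


def test_tilted_ring_axis_ratio():
    """A ring tilted 60 deg from face-on projects to an ellipse with axis
    ratio cos(60) = 0.5, up to polygonal/perspective error."""
    pose = straight_pose()
    D = 200.0  # far away: near-orthographic, so the conic ratio is clean
    center = pose.position + D * pose.view_dir
    tilt = math.radians(60.0)
    normal = -math.cos(tilt) * pose.view_dir + math.sin(tilt) * np.array([1.0, 0, 0])
    tgt = TargetMarker(id=1, center=center, normal=normal)
    ring = project_ring(tgt, pose, CAM)
    rel = ring.outer_boundary - ring.outer_boundary.mean(axis=0)
    svals = np.linalg.svd(rel, compute_uv=False)
    ratio = svals[1] / svals[0]
    assert ratio == pytest.approx(0.5, rel=0.02)


def test_ring_vertices_equal_pointwise_projection(rng):
    pose = pose_from_shaft(0.1, 0.2, 20.0, -30.0, GEOM)
    center = pose.position + 35.0 * pose.view_dir
    tgt = TargetMarker(id=2, center=center, normal=-pose.view_dir)
    ring = project_ring(tgt, pose, CAM, n_vertices=64)
    from scopeskill.optics import _circle_points_3d

    pts3 = _circle_points_3d(tgt.center, tgt.normal, tgt.ring_outer_radius, 64)
    for p3, px in zip(pts3, ring.outer_boundary):
        assert np.allclose(project_point(p3, pose, CAM), px, atol=1e-9)


def test_ring_behind_camera_not_visible():
    pose = straight_pose()
    tgt = TargetMarker(id=1, center=pose.position - 20.0 * pose.view_dir,
                       normal=pose.view_dir)
    with pytest.raises(NotVisibleError):
        project_ring(tgt, pose, CAM)


def test_grazing_ring_degenerate():
    pose = straight_pose()
    center = pose.position + 40.0 * pose.view_dir
    normal = np.cross(pose.view_dir, [0, 1, 0])  # ring plane contains the ray
    tgt = TargetMarker(id=1, center=center, normal=normal / np.linalg.norm(normal))
    with pytest.raises(ObliqueDegenerateError):
        project_ring(tgt, pose, CAM)


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def test_score_trivial_inside_and_outside():
    overlay = OverlayEllipse(semi_major=20, semi_minor=15)
    big = circle_ring(120.0, CAM.principal_point)
    assert accuracy_score(overlay, big, CAM) == pytest.approx(100.0, abs=1e-9)
    assert is_focused(overlay, big, CAM)
    far = circle_ring(30.0, (CAM.principal_point[0] + 300, CAM.principal_point[1]))
    assert accuracy_score(overlay, far, CAM) == pytest.approx(0.0, abs=1e-9)
    assert not is_focused(overlay, far, CAM)


def test_tangent_from_inside_is_focused():
    overlay = OverlayEllipse(semi_major=50, semi_minor=50)
    ring = circle_ring(50.0, CAM.principal_point)   # same 128-gon radius
    assert is_focused(overlay, ring, CAM, tol=1e-6)


def test_half_overlap_matches_lens_formula_and_raster_oracle():
    """Equal circles with centres one radius apart: overlap fraction is the
    two-circle lens area, ~39.1%; the clipper must agree with both the
    closed form and the rasterization oracle."""
    R = 60.0
    overlay = OverlayEllipse(semi_major=R, semi_minor=R)
    ring = circle_ring(R, (CAM.principal_point[0] + R, CAM.principal_point[1]))
    score = accuracy_score(overlay, ring, CAM)
    lens_frac = (2 * math.pi / 3 - math.sqrt(3) / 2) / math.pi * 100.0
    assert score == pytest.approx(lens_frac, abs=0.5)
    assert score == pytest.approx(rasterized_score(overlay, ring, CAM), abs=0.5)


@pytest.mark.parametrize("shift", [0.0, 20.0, 45.0, 80.0, 130.0])
def test_score_monotone_in_translation(shift):
    overlay = OverlayEllipse(semi_major=40, semi_minor=28)
    s1 = accuracy_score(overlay, circle_ring(
        60.0, (CAM.principal_point[0] + shift, CAM.principal_point[1])), CAM)
    s2 = accuracy_score(overlay, circle_ring(
        60.0, (CAM.principal_point[0] + shift + 10.0, CAM.principal_point[1])), CAM)
    assert s2 <= s1 + 1e-9


def test_score_99_5_is_not_focused():
    overlay = OverlayEllipse(semi_major=40, semi_minor=28)
    # slide the ring until the score drops just below 100
    for shift in np.linspace(20, 120, 300):
        ring = circle_ring(60.0, (CAM.principal_point[0] + shift,
                                  CAM.principal_point[1]))
        s = accuracy_score(overlay, ring, CAM)
        if s < 100.0 - 1e-9:
            assert not is_focused(overlay, ring, CAM)
            break
    else:
        pytest.fail("never left the focused region")


def test_score_rotation_invariance():
    """Rotating a circular overlay and the ring together about the principal
    point leaves the score unchanged (rigid-motion invariance)."""
    overlay = OverlayEllipse(semi_major=35, semi_minor=35)
    cx, cy = CAM.principal_point
    s_ref = accuracy_score(overlay, circle_ring(40.0, (cx + 30.0, cy)), CAM)
    for ang in (30.0, 90.0, 215.0):
        r = math.radians(ang)
        center = (cx + 30.0 * math.cos(r), cy + 30.0 * math.sin(r))
        s = accuracy_score(overlay, circle_ring(40.0, center), CAM)
        assert s == pytest.approx(s_ref, abs=0.05)


def test_difficulty_monotone_in_overlay_size(rng):
    """Growing the overlay (harder focus) never increases the score, for any
    ring whose region contains the reticle centre."""
    for _ in range(20):
        radius = rng.uniform(30, 80)
        off = rng.uniform(0, 0.8 * radius)
        ang = rng.uniform(0, 2 * math.pi)
        center = (CAM.principal_point[0] + off * math.cos(ang),
                  CAM.principal_point[1] + off * math.sin(ang))
        ring = circle_ring(radius, center)
        scores = [accuracy_score(OverlayEllipse(semi_major=a, semi_minor=0.7 * a),
                                 ring, CAM)
                  for a in (20.0, 35.0, 50.0, 70.0)]
        assert all(s2 <= s1 + 1e-9 for s1, s2 in zip(scores, scores[1:]))


def test_clipper_vs_raster_oracle_random(rng):
    """Polygon clipping agrees with the rasterization oracle on random
    overlay/ring configurations."""
    for i in range(25):
        overlay = OverlayEllipse(semi_major=rng.uniform(20, 60),
                                 semi_minor=rng.uniform(10, 20),
                                 orientation_deg=rng.uniform(0, 180))
        center = (CAM.principal_point[0] + rng.uniform(-80, 80),
                  CAM.principal_point[1] + rng.uniform(-80, 80))
        ring = circle_ring(rng.uniform(25, 90), center)
        s = accuracy_score(overlay, ring, CAM)
        assert s == pytest.approx(
            rasterized_score(overlay, ring, CAM, n_samples=100_000, seed=i),
            abs=0.5)


def test_fast_proxy_tracks_exact_score(setup):
    """The agent's cheap perceived score stays close to the exact clipper."""
    for tid, pose in setup.ideal_poses.items():
        tgt = setup.target_by_id(tid)
        exact = accuracy_score(setup.overlay, project_ring(tgt, pose, setup.cam),
                               setup.cam)
        fast = focus_score_fast(pose, tgt, setup.cam, setup.overlay)
        assert abs(exact - fast) <= 8.0


def test_ellipse_polygon_area():
    ov = OverlayEllipse(semi_major=40, semi_minor=28)
    poly = ellipse_polygon(ov, (0.0, 0.0), n_vertices=256)
    # shoelace area of the 256-gon vs pi*a*b
    x, y = poly[:, 0], poly[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    assert area == pytest.approx(math.pi * 40 * 28, rel=1e-3)
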