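"""Projective geometry: DLT, triangulation, rigid fits, pose arithmetic."""

import numpy as np
import pytest

from noarsa.geometry import (
    GeometryError,
    MarkerSet,
    Pose6,
    ProjectionModel,
    RigidTransform,
    dlt_calibrate,
    pose_error,
    pose_to_transform,
    project,
    rigid_fit,
    transform_to_pose,
    triangulate,
)
from noarsa.phantom import make_stereo_rig


def identity_camera(size=100):
    return ProjectionModel(np.hstack([np.eye(3), np.zeros((3, 1))]), size, size, 1.0)


# --------------------------------------------------------------------------- #
# projection


@pytest.mark.parametrize(
    "point,expected",
    [((0.0, 0.0, 1.0), (0.0, 0.0)), ((1.0, 1.0, 2.0), (0.5, 0.5))],
)
def test_project_canonical_camera(point, expected):
    assert np.allclose(project(identity_camera(), np.array(point)), expected)


def test_project_matches_homogeneous_arithmetic():
    m = np.array(
        [[200.0, 3.0, 150.0, 40.0], [-1.0, 210.0, 140.0, -7.0], [0.01, 0.02, 1.0, 2.0]]
    )
    cam = ProjectionModel(m, 320, 320, 0.5)
    p = np.array([12.0, -4.0, 9.0])
    h = m @ np.append(p, 1.0)
    assert np.allclose(project(cam, p), h[:2] / h[2], atol=1e-12)


def test_project_rejects_point_behind_source():
    with pytest.raises(GeometryError):
        project(identity_camera(), np.array([0.0, 0.0, -1.0]))


# --------------------------------------------------------------------------- #
# DLT calibration


def test_dlt_recovers_generating_camera():
    """Noise-free bead correspondences reproject with sub-1e-8 px RMS."""
    cams, cage, proj = make_stereo_rig(pixel_spacing=0.5)
    for cam, xy in zip(cams, proj):
        model, rms = dlt_calibrate(
            cage, xy, cam.image_width, cam.image_height, cam.pixel_spacing
        )
        assert rms < 1e-8
        re_xy, depth = model.project_points(cage.points)
        assert np.all(depth > 0)
        assert np.allclose(re_xy, xy, atol=1e-7)


def test_dlt_identity_case(rng):
    pts = rng.uniform(-1.0, 1.0, (12, 3))
    pts[:, 2] = rng.uniform(2.0, 5.0, 12)  # strictly in front
    cam0 = identity_camera()
    xy, _ = cam0.project_points(pts)
    model, rms = dlt_calibrate(pts, xy, 100, 100, 1.0)
    assert rms < 1e-10
    xy2, _ = model.project_points(pts)
    assert np.allclose(xy2, xy, atol=1e-9)


def test_dlt_underdetermined():
    pts = np.random.default_rng(0).uniform(0, 1, (5, 3))
    with pytest.raises(GeometryError, match="[Ii]nsufficient"):
        dlt_calibrate(pts, pts[:, :2])


def test_dlt_coplanar_degenerate(rng):
    pts = rng.uniform(-1, 1, (10, 3))
    pts[:, 2] = 4.0  # all on one plane
    xy, _ = identity_camera().project_points(pts)
    with pytest.raises(GeometryError, match="coplanar"):
        dlt_calibrate(pts, xy)


# --------------------------------------------------------------------------- #
# triangulation


def test_triangulate_projection_roundtrip():
    cams, _, _ = make_stereo_rig(pixel_spacing=0.5)
    p = np.array([13.0, -42.0, 8.0])
    xy = [cam.project_points(p.reshape(1, 3))[0][0] for cam in cams]
    rec, residual = triangulate(cams[0], cams[1], xy[0], xy[1])
    assert np.allclose(rec, p, atol=1e-8)
    assert residual < 1e-8


def test_triangulate_under_pixel_noise():
    """With 0.1 px Gaussian noise, 3D error stays below 5x pixel spacing."""
    cams, _, _ = make_stereo_rig(pixel_spacing=0.5)
    gen = np.random.default_rng(7)
    errors = []
    for _ in range(100):
        p = gen.uniform(-60, 60, 3)
        xy = [
            cam.project_points(p.reshape(1, 3))[0][0] + 0.1 * gen.standard_normal(2)
            for cam in cams
        ]
        rec, _ = triangulate(cams[0], cams[1], xy[0], xy[1])
        errors.append(np.linalg.norm(rec - p))
    assert max(errors) < 5 * 0.5


def test_triangulate_identical_cameras_degenerate():
    cam = identity_camera()
    with pytest.raises(GeometryError, match="parallel"):
        triangulate(cam, cam, np.array([1.0, 2.0]), np.array([1.0, 2.0]))


# --------------------------------------------------------------------------- #
# rigid fit


def test_rigid_fit_identity(rng):
    pts = rng.uniform(-50, 50, (10, 3))
    t, rmsd = rigid_fit(pts, pts)
    assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
    assert np.allclose(t.translation, 0, atol=1e-12)
    assert rmsd < 1e-12


def test_rigid_fit_recovers_known_motion(rng):
    src = rng.uniform(-50, 50, (10, 3))
    truth = pose_to_transform(Pose6(rz=30.0, tx=5.0, ty=-2.0, tz=11.0))
    t, rmsd = rigid_fit(src, truth.apply(src))
    assert np.allclose(t.rotation, truth.rotation, atol=1e-9)
    assert np.allclose(t.translation, truth.translation, atol=1e-9)
    assert rmsd < 1e-9


def test_rigid_fit_returns_proper_rotation_for_mirrored_points(rng):
    src = rng.uniform(-10, 10, (8, 3))
    dst = src * np.array([-1.0, 1.0, 1.0])  # reflection-only correspondence
    t, _ = rigid_fit(src, dst)
    assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-12)


def test_rigid_fit_rmsd_invariant_under_common_rigid_motion(rng):
    src = rng.uniform(-20, 20, (10, 3))
    dst = src + rng.normal(0, 0.5, src.shape)  # non-rigid correspondence noise
    _, rmsd0 = rigid_fit(src, dst)
    pre = pose_to_transform(Pose6(rx=17.0, ry=-40.0, rz=5.0, tx=3.0, ty=8.0, tz=-2.0))
    _, rmsd1 = rigid_fit(pre.apply(src), pre.apply(dst))
    assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)


def test_rigid_fit_requires_three_noncollinear_points():
    line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(GeometryError, match="collinear"):
        rigid_fit(line, line)
    with pytest.raises(GeometryError):
        rigid_fit(line[:2], line[:2])


# --------------------------------------------------------------------------- #
# pose parametrization


def test_zero_pose_is_identity():
    t = pose_to_transform(Pose6())
    assert np.allclose(t.rotation, np.eye(3))
    assert np.allclose(t.translation, 0)


def test_x_rotation_maps_y_to_z():
    t = pose_to_transform(Pose6(rx=90.0))
    assert np.allclose(t.apply(np.array([0.0, 1.0, 0.0])), [0.0, 0.0, 1.0], atol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_pose_transform_roundtrip(seed):
    gen = np.random.default_rng(seed)
    pose = Pose6.from_vector(gen.uniform(-45, 45, 6), gen.uniform(-30, 30, 3))
    back = transform_to_pose(pose_to_transform(pose), pose.rotation_center)
    assert np.allclose(back.as_vector(), pose.as_vector(), atol=1e-10)


def test_pure_translations_compose_additively(rng):
    center = rng.uniform(-10, 10, 3)
    t1 = rng.uniform(-5, 5, 3)
    t2 = rng.uniform(-5, 5, 3)
    a = pose_to_transform(Pose6(tx=t1[0], ty=t1[1], tz=t1[2], rotation_center=center))
    b = pose_to_transform(Pose6(tx=t2[0], ty=t2[1], tz=t2[2], rotation_center=center))
    s = t1 + t2
    ab = a.compose(b)
    direct = pose_to_transform(
        Pose6(tx=s[0], ty=s[1], tz=s[2], rotation_center=center)
    )
    assert np.allclose(ab.rotation, direct.rotation, atol=1e-12)
    assert np.allclose(ab.translation, direct.translation, atol=1e-12)


def test_pose_error_basics():
    a = Pose6(rx=1.0, ry=2.0, tz=-3.0)
    assert np.allclose(pose_error(a, a), 0)
    b = Pose6(rx=1.0, ry=2.5, tz=-3.0)
    assert np.allclose(pose_error(a, b), [0, 0.5, 0, 0, 0, 0])


def test_pose_error_absolute_per_axis_magnitudes():
    """Differencing a perturbed pose against zero recovers the perturbation
    magnitudes per axis: (4.59, 3.68, 2.38) deg and (1.31, 1.07, 1.03) mm."""
    perturbed = Pose6(rx=4.59, ry=-3.68, rz=-2.38, tx=-1.31, ty=1.07, tz=-1.03)
    err = pose_error(Pose6(), perturbed)
    assert np.allclose(err, [4.59, 3.68, 2.38, 1.31, 1.07, 1.03])


def test_pose_error_rejects_mismatched_rotation_centers():
    a = Pose6(rotation_center=[0.0, 0.0, 0.0])
    b = Pose6(rotation_center=[1.0, 0.0, 0.0])
    with pytest.raises(GeometryError):
        pose_error(a, b)


def test_rigid_transform_rejects_reflection():
    with pytest.raises(GeometryError):
        RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
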