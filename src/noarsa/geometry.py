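"""Projective geometry for stereo radiostereometric analysis.

Implements the camera model and pose machinery the registration is built on:

* :class:`ProjectionModel` — an 11-parameter direct linear transformation
  (DLT) camera, i.e. a 3x4 homogeneous matrix mapping world millimetres to
  continuous pixel coordinates of one radiographic view.
* :func:`dlt_calibrate` — least-squares DLT solve from bead correspondences
  (calibration cage), with Hartley-style point normalization.
* :func:`triangulate` — linear two-view triangulation of a tantalum bead.
* :func:`rigid_fit` — orthogonal-Procrustes (Kabsch) rigid registration of
  corresponded marker sets, used to express marker-based ground-truth poses.
* :class:`Pose6` — the six-DOF pose vector optimized by the registration:
  three rotations in degrees and three translations in millimetres about a
  fixed rotation center.

Conventions: image origin at the top-left pixel *center*, x right / y down,
0-based continuous pixel units; angles always degrees, lengths always mm.
Euler angles are fixed-axis (extrinsic) X then Y then Z, right-handed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "GeometryError",
    "ProjectionModel",
    "Pose6",
    "RigidTransform",
    "MarkerSet",
    "dlt_calibrate",
    "project",
    "triangulate",
    "rigid_fit",
    "pose_to_transform",
    "transform_to_pose",
    "pose_error",
]


class GeometryError(ValueError):
    """Degenerate configuration (underdetermined calibration, parallel rays, ...)."""


# --------------------------------------------------------------------------- #
# camera model


@dataclass(frozen=True)
class ProjectionModel:
    """A 3x4 homogeneous projection for one radiographic view.

    The matrix is defined up to scale; fixing the last element to 1 yields the
    classical 11 DLT parameters.  ``pixel_spacing`` is the physical detector
    pixel size in mm/px and is metadata for the owning view (the matrix itself
    already maps to pixel units).
    """

    matrix: np.ndarray
    image_width: int
    image_height: int
    pixel_spacing: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 4):
            raise GeometryError(f"projection matrix must be 3x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise GeometryError("projection matrix contains non-finite values")
        if np.linalg.matrix_rank(m) < 3:
            raise GeometryError("projection matrix is rank deficient")
        object.__setattr__(self, "matrix", m)

    @property
    def dlt_parameters(self) -> np.ndarray:
        """The 11 DLT parameters (matrix scaled so its last element is 1)."""
        m = self.matrix
        if abs(m[2, 3]) < 1e-300:
            raise GeometryError("last matrix element is zero; cannot normalize")
        return (m / m[2, 3]).ravel()[:11]

    def project_points(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project an (N, 3) array of world points.

        Returns ``(xy, depth)`` where ``xy`` is (N, 2) in continuous pixels and
        ``depth`` is the homogeneous scale; positive depth means in front of
        the X-ray source.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = pts @ self.matrix[:, :3].T + self.matrix[:, 3]
        depth = h[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            xy = h[:, :2] / depth[:, None]
        return xy, depth

    def center(self) -> np.ndarray:
        """The X-ray source position (null space of the matrix), in mm."""
        _, _, vt = np.linalg.svd(self.matrix)
        c = vt[-1]
        if abs(c[3]) < 1e-12:
            raise GeometryError("camera center at infinity")
        return c[:3] / c[3]

    def ray_direction(self, xy: np.ndarray) -> np.ndarray:
        """Unit direction of the viewing ray through pixel ``xy``."""
        x, y = float(xy[0]), float(xy[1])
        d = np.linalg.solve(self.matrix[:, :3], np.array([x, y, 1.0]))
        return d / np.linalg.norm(d)


def project(camera: ProjectionModel, point: np.ndarray) -> np.ndarray:
    """Project one 3D point (mm) to continuous pixel coordinates.

    Raises :class:`GeometryError` if the point is at or behind the source
    plane (non-positive homogeneous depth).
    """
    xy, depth = camera.project_points(np.asarray(point, dtype=float).reshape(1, 3))
    if depth[0] <= 0:
        raise GeometryError("point has non-positive depth (behind the source)")
    return xy[0]


# --------------------------------------------------------------------------- #
# markers and rigid transforms


@dataclass(frozen=True)
class MarkerSet:
    """Labelled 3D marker positions (mm) in a named frame."""

    labels: tuple[str, ...]
    points: np.ndarray  # (N, 3)
    frame: str = "world"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError("marker points must be (N, 3)")
        if len(self.labels) != len(pts):
            raise GeometryError("label/point count mismatch")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("marker coordinates must be finite")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion: ``x -> R x + t`` with det(R) = +1."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if r.shape != (3, 3):
            raise GeometryError("rotation must be 3x3")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise GeometryError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise GeometryError("rotation is a reflection (det < 0)")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


# --------------------------------------------------------------------------- #
# six-DOF pose


@dataclass
class Pose6:
    """Six-DOF pose: rotations in degrees, translations in mm.

    The rigid motion is: rotate about ``rotation_center`` by fixed-axis
    X -> Y -> Z Euler angles, then translate by ``(tx, ty, tz)``.  Storing the
    angles in degrees lets one coarse-to-fine difference-spacing schedule
    cover both rotational and translational degrees of freedom.
    """

    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rotation_center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation_center = np.asarray(self.rotation_center, dtype=float).reshape(3)

    def as_vector(self) -> np.ndarray:
        """DOF vector ordered ``(rx, ry, rz, tx, ty, tz)``."""
        return np.array([self.rx, self.ry, self.rz, self.tx, self.ty, self.tz])

    @staticmethod
    def from_vector(v: np.ndarray, rotation_center: np.ndarray) -> "Pose6":
        v = np.asarray(v, dtype=float).reshape(6)
        return Pose6(*v, rotation_center=np.array(rotation_center, dtype=float))

    def perturbed(self, dof: int, delta: float) -> "Pose6":
        """Copy of this pose with DOF ``dof`` (0..5) offset by ``delta``."""
        v = self.as_vector()
        v[dof] += delta
        return Pose6.from_vector(v, self.rotation_center)


def pose_to_transform(pose: Pose6) -> RigidTransform:
    """Rigid motion of a :class:`Pose6` (rotate about center, then translate)."""
    r = Rotation.from_euler(
        "xyz", [pose.rx, pose.ry, pose.rz], degrees=True
    ).as_matrix()
    c = pose.rotation_center
    t = c - r @ c + np.array([pose.tx, pose.ty, pose.tz])
    return RigidTransform(r, t)


def transform_to_pose(transform: RigidTransform, rotation_center: np.ndarray) -> Pose6:
    """Inverse of :func:`pose_to_transform` for a given rotation center."""
    c = np.asarray(rotation_center, dtype=float).reshape(3)
    angles = Rotation.from_matrix(transform.rotation).as_euler("xyz", degrees=True)
    t = transform.translation - c + transform.rotation @ c
    return Pose6(*angles, *t, rotation_center=c)


def pose_error(a: Pose6, b: Pose6) -> np.ndarray:
    """Per-axis absolute pose differences ``(|drx|,|dry|,|drz|,|dtx|,|dty|,|dtz|)``.

    Rotations in degrees, translations in mm.  Both poses must share the same
    rotation center, otherwise the parameterizations are not comparable.
    """
    if not np.allclose(a.rotation_center, b.rotation_center, atol=1e-9):
        raise GeometryError("poses have different rotation centers")
    return np.abs(a.as_vector() - b.as_vector())


# --------------------------------------------------------------------------- #
# DLT calibration


def _normalize_2d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(2.0) / d if d > 0 else 1.0
    t = np.array([[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]])
    ones = np.ones((len(pts), 1))
    return (np.hstack([pts, ones]) @ t.T)[:, :2], t


def _normalize_3d(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1).mean()
    s = np.sqrt(3.0) / d if d > 0 else 1.0
    t = np.eye(4)
    t[:3, :3] *= s
    t[:3, 3] = -s * centroid
    ones = np.ones((len(pts), 1))
    return (np.hstack([pts, ones]) @ t.T)[:, :3], t


def dlt_calibrate(
    world_points: MarkerSet | np.ndarray,
    image_points: np.ndarray,
    image_width: int | None = None,
    image_height: int | None = None,
    pixel_spacing: float = 1.0,
) -> tuple[ProjectionModel, float]:
    """Solve the 11-parameter DLT camera from 3D-2D bead correspondences.

    Uses Hartley point normalization for conditioning and the smallest
    right-singular vector of the stacked homogeneous system.  Returns the
    calibrated :class:`ProjectionModel` and the reprojection RMS in pixels.

    Requires at least 6 correspondences with non-coplanar world points.
    """
    world = world_points.points if isinstance(world_points, MarkerSet) else np.asarray(world_points, dtype=float)
    img = np.asarray(image_points, dtype=float)
    if world.ndim != 2 or world.shape[1] != 3 or img.shape != (len(world), 2):
        raise GeometryError("need matching (N,3) world and (N,2) image points")
    n = len(world)
    if n < 6:
        raise GeometryError(f"insufficient correspondences for DLT: {n} < 6")
    # coplanarity check: smallest principal extent relative to the largest
    sv = np.linalg.svd(world - world.mean(axis=0), compute_uv=False)
    if sv[2] < 1e-8 * sv[0]:
        raise GeometryError("world points are (near-)coplanar; DLT is degenerate")

    xw, tw = _normalize_3d(world)
    xi, ti = _normalize_2d(img)
    a = np.zeros((2 * n, 12))
    for k in range(n):
        x, y, z = xw[k]
        u, v = xi[k]
        a[2 * k] = [x, y, z, 1, 0, 0, 0, 0, -u * x, -u * y, -u * z, -u]
        a[2 * k + 1] = [0, 0, 0, 0, x, y, z, 1, -v * x, -v * y, -v * z, -v]
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-10 * s[0]:
        raise GeometryError("degenerate correspondence configuration")
    p = vt[-1].reshape(3, 4)
    p = np.linalg.inv(ti) @ p @ tw
    # orient the matrix so the calibration beads have positive depth
    depths = world @ p[2, :3] + p[2, 3]
    if np.median(depths) < 0:
        p = -p
    p /= np.linalg.norm(p[2, :3])

    if image_width is None:
        image_width = int(np.ceil(img[:, 0].max())) + 1
    if image_height is None:
        image_height = int(np.ceil(img[:, 1].max())) + 1
    model = ProjectionModel(p, image_width, image_height, pixel_spacing)
    xy, _ = model.project_points(world)
    rms = float(np.sqrt(np.mean(np.sum((xy - img) ** 2, axis=1))))
    return model, rms


# --------------------------------------------------------------------------- #
# triangulation


def triangulate(
    cam_a: ProjectionModel,
    cam_b: ProjectionModel,
    xy_a: np.ndarray,
    xy_b: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Linear (DLT) triangulation of one point seen in two views.

    Minimizes the algebraic error of the stacked homogeneous constraints.
    Returns the 3D point in mm and the mean reprojection distance in pixels.
    Near-parallel viewing rays raise :class:`GeometryError`.
    """
    xy_a = np.asarray(xy_a, dtype=float).reshape(2)
    xy_b = np.asarray(xy_b, dtype=float).reshape(2)
    da = cam_a.ray_direction(xy_a)
    db = cam_b.ray_direction(xy_b)
    if abs(abs(float(da @ db)) - 1.0) < 1e-10:
        raise GeometryError("viewing rays are (near-)parallel; triangulation degenerate")

    rows = []
    for cam, (u, v) in ((cam_a, xy_a), (cam_b, xy_b)):
        m = cam.matrix
        rows.append(u * m[2] - m[0])
        rows.append(v * m[2] - m[1])
    a = np.asarray(rows)
    _, _, vt = np.linalg.svd(a)
    xh = vt[-1]
    if abs(xh[3]) < 1e-14:
        raise GeometryError("triangulated point at infinity")
    x = xh[:3] / xh[3]
    ra, _ = cam_a.project_points(x)
    rb, _ = cam_b.project_points(x)
    residual = 0.5 * (
        np.linalg.norm(ra[0] - xy_a) + np.linalg.norm(rb[0] - xy_b)
    )
    return x, float(residual)


# --------------------------------------------------------------------------- #
# rigid point-set registration


def rigid_fit(
    src: MarkerSet | np.ndarray, dst: MarkerSet | np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid registration of corresponded marker sets (Kabsch).

    Finds the proper rotation and translation minimizing
    ``sum_i ||R src_i + t - dst_i||^2`` and returns it with the RMSD in mm.
    A reflection in the optimal orthogonal solution is corrected to a proper
    rotation (det = +1).
    """
    s = src.points if isinstance(src, MarkerSet) else np.asarray(src, dtype=float)
    d = dst.points if isinstance(dst, MarkerSet) else np.asarray(dst, dtype=float)
    if s.shape != d.shape or s.ndim != 2 or s.shape[1] != 3:
        raise GeometryError("need matching (N,3) point sets")
    if len(s) < 3:
        raise GeometryError("rigid fit requires at least 3 points")
    sc, dc = s.mean(axis=0), d.mean(axis=0)
    s0, d0 = s - sc, d - dc
    if np.linalg.svd(s0, compute_uv=False)[1] < 1e-9 * max(1.0, np.abs(s0).max()):
        raise GeometryError("source points are (near-)collinear")
    h = s0.T @ d0
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, sign if sign != 0 else 1.0])
    r = vt.T @ corr @ u.T
    t = dc - r @ sc
    transform = RigidTransform(r, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(s) - d) ** 2, axis=1))))
    return transform, rmsd
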