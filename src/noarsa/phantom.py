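"""Synthetic phantom: stem mesh, biplanar stereo rig, virtual radiographs.

Everything needed to exercise the NOA registration without any external data:

* :func:`make_stem_mesh` — a watertight, asymmetric femoral-stem-like surface
  (tapered, twisted, laterally offset elliptical cross sections, ~150 mm
  tall) with an off-axis ball head.  The asymmetry is what makes the pose
  observable from two silhouettes, in particular the rotation about the
  proximodistal (y) axis.
* :func:`make_stereo_rig` — two pinhole DLT cameras whose principal rays
  intersect at the scene origin at a configurable angle (default 90°, the
  anterior-posterior / lateral setup), plus a 36-bead biplanar calibration
  cage with exact per-view projections.
* :func:`simulate_radiograph` — noise-free binary silhouettes or noisy
  high-contrast grayscale radiographs of the posed implant.
* :func:`run_insilico_experiment` — the evaluation harness: registrations
  from random initial offsets at several pixel spacings, summarized as
  per-axis mean +/- SD absolute errors, iteration counts and relative NOA.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .geometry import GeometryError, MarkerSet, Pose6, ProjectionModel, pose_error, pose_to_transform
from .imaging import DropoutMask, Radiograph
from .registration import DEFAULT_SCHEDULE, View, register
from .renderer import TriangleMesh, render_silhouette

__all__ = [
    "PhantomScene",
    "ExperimentConfig",
    "STEM_HEAD_CENTER",
    "make_stem_mesh",
    "make_stereo_rig",
    "make_scene",
    "simulate_radiograph",
    "sample_initial_poses",
    "make_dropout_scenario",
    "apply_occluder",
    "run_insilico_experiment",
    "summarize_trials",
]

# stem construction constants (mm); the ball head sits proximally, offset
# laterally and anteriorly like a femoral neck, which gives the silhouettes
# a strong y-rotation signal
_STEM_Y_BOTTOM = -100.0
_STEM_Y_TOP = 55.0
# cross-section superellipse exponent (2 = ellipse; smooth boundaries keep
# the pixel-flip landscape well conditioned for the optimizer)
_SECTION_EXPONENT = 2.0
_HEAD_RADIUS = 14.0
#: Center of the ball head in the mesh frame (before posing), mm.  The
#: lateral offset matches the ~40 mm femoral offset of revision stems; it is
#: the dominant lever arm for observing rotation about the proximodistal axis.
STEM_HEAD_CENTER = np.array([40.0, 71.0, 6.0])


def make_stem_mesh(
    seed: int = 1, n_segments: int = 96, n_around: int | None = None
) -> TriangleMesh:
    """Build the synthetic femoral-stem mesh (watertight, asymmetric).

    The stem is a loft of ``n_segments + 1`` elliptical cross sections from
    distal (narrow) to proximal (wide), twisted by 30 degrees about the
    proximodistal axis and bowed laterally, capped at both ends; the ball
    head is an icosphere centered at :data:`STEM_HEAD_CENTER`.  The profile
    is modulated by a smooth low-frequency shape variation drawn from
    ``seed`` (eight control radii, linearly interpolated) so distinct seeds
    give distinct but physically smooth implants; the same seed is
    bit-reproducible.  The default tessellation is deliberately fine: the
    registration operates on undecimated high-polygon surface models, and a
    smooth silhouette boundary is part of the study conditions.
    """
    if n_segments < 8:
        raise ValueError("n_segments must be >= 8")
    if n_around is None:
        n_around = n_segments
    rng = np.random.default_rng(seed)
    control = 1.0 + 0.03 * rng.standard_normal(8)
    t_all = np.arange(n_segments + 1) / n_segments
    jitter = np.interp(t_all, np.linspace(0.0, 1.0, 8), control)

    verts: list[np.ndarray] = []
    for i in range(n_segments + 1):
        t = t_all[i]
        y = _STEM_Y_BOTTOM + t * (_STEM_Y_TOP - _STEM_Y_BOTTOM)
        a = (5.0 + 9.0 * t) * jitter[i]  # semi-axis in x
        b = (4.0 + 5.0 * t) * jitter[i]  # semi-axis in z
        cx = 8.0 * t * t  # lateral bow toward the neck side
        cz = 1.5 * np.sin(np.pi * t)
        phi = np.deg2rad(30.0) * t  # twist about y
        theta = 2.0 * np.pi * np.arange(n_around) / n_around
        e = 2.0 / _SECTION_EXPONENT
        ct, st = np.cos(theta), np.sin(theta)
        lx = a * np.sign(ct) * np.abs(ct) ** e
        lz = b * np.sign(st) * np.abs(st) ** e
        ring = np.column_stack(
            [
                cx + lx * np.cos(phi) + lz * np.sin(phi),
                np.full(n_around, y),
                cz - lx * np.sin(phi) + lz * np.cos(phi),
            ]
        )
        verts.append(ring)
    vertices = np.vstack(verts)

    faces: list[tuple[int, int, int]] = []
    for i in range(n_segments):
        base0 = i * n_around
        base1 = (i + 1) * n_around
        for j in range(n_around):
            k = (j + 1) % n_around
            faces.append((base0 + j, base1 + j, base1 + k))
            faces.append((base0 + j, base1 + k, base0 + k))
    # end caps (fans around the ring centroids)
    bottom_center = len(vertices)
    top_center = bottom_center + 1
    vertices = np.vstack([vertices, verts[0].mean(axis=0), verts[-1].mean(axis=0)])
    for j in range(n_around):
        k = (j + 1) % n_around
        faces.append((bottom_center, k, j))
        top0 = n_segments * n_around
        faces.append((top_center, top0 + j, top0 + k))

    head = trimesh.creation.icosphere(subdivisions=4, radius=_HEAD_RADIUS)
    offset = len(vertices)
    vertices = np.vstack([vertices, np.asarray(head.vertices) + STEM_HEAD_CENTER])
    all_faces = np.vstack([np.asarray(faces), np.asarray(head.faces) + offset])
    return TriangleMesh(vertices, all_faces)


def make_stereo_rig(
    angle_deg: float = 90.0,
    source_distance_mm: float = 1000.0,
    pixel_spacing: float = 0.5,
    image_size: int | None = None,
    detector_width_mm: float = 300.0,
    source_detector_mm: float = 1200.0,
) -> tuple[tuple[ProjectionModel, ProjectionModel], MarkerSet, list[np.ndarray]]:
    """Biplanar stereo rig with a 36-bead calibration cage.

    Both views are pinhole projections whose principal rays meet at the scene
    origin with the given angle between them (view 0 is anterior-posterior,
    view 1 lateral, separated by rotating about the proximodistal y axis).
    Returns the two cameras, the cage bead positions (two parallel planes of
    18 beads) and the exact 2D bead projections per view.
    """
    if not 20.0 <= angle_deg <= 160.0:
        raise GeometryError("stereo angle must lie in [20, 160] degrees")
    if image_size is None:
        image_size = int(round(detector_width_mm / pixel_spacing))

    cameras = []
    for alpha in (0.0, np.deg2rad(angle_deg)):
        u = np.array([np.sin(alpha), 0.0, np.cos(alpha)])  # origin -> source
        source = source_distance_mm * u
        z_cam = -u
        y_cam = np.array([0.0, -1.0, 0.0])  # world up maps to image up (row 0)
        x_cam = np.cross(y_cam, z_cam)
        rot = np.vstack([x_cam, y_cam, z_cam])
        f_px = source_detector_mm / pixel_spacing
        c = (image_size - 1) / 2.0
        k = np.array([[f_px, 0.0, c], [0.0, f_px, c], [0.0, 0.0, 1.0]])
        p = k @ np.hstack([rot, (-rot @ source)[:, None]])
        p /= np.linalg.norm(p[2, :3])
        cameras.append(ProjectionModel(p, image_size, image_size, pixel_spacing))

    xs = np.linspace(-80.0, 80.0, 6)
    ys = np.array([-90.0, 0.0, 90.0])
    beads = [
        (x, y, z) for z in (-80.0, 80.0) for y in ys for x in xs
    ]
    cage = MarkerSet(
        tuple(f"bead{i:02d}" for i in range(len(beads))),
        np.asarray(beads, dtype=float),
        frame="cage",
    )
    projections = []
    for cam in cameras:
        xy, depth = cam.project_points(cage.points)
        assert np.all(depth > 0)
        projections.append(xy)
    return (cameras[0], cameras[1]), cage, projections


@dataclass
class PhantomScene:
    """A complete, seeded in silico scene for one pixel spacing."""

    mesh: TriangleMesh
    ground_truth_pose: Pose6
    cameras: tuple[ProjectionModel, ProjectionModel]
    cage_markers: MarkerSet
    cage_projections: list[np.ndarray]
    phantom_markers: MarkerSet
    head_center: np.ndarray
    pixel_spacing: float
    seed: int

    @property
    def lever_mm(self) -> float:
        """Largest vertex distance from the rotation center (for ROI margins)."""
        return float(
            np.linalg.norm(self.mesh.vertices - self.ground_truth_pose.rotation_center, axis=1).max()
        )


def make_scene(
    seed: int = 1,
    pixel_spacing: float = 0.5,
    angle_deg: float = 90.0,
    n_segments: int = 96,
    source_distance_mm: float = 1000.0,
    source_detector_mm: float = 1200.0,
    detector_width_mm: float = 300.0,
) -> PhantomScene:
    """Assemble mesh, rig and a seeded ground-truth pose into one scene.

    The ground-truth pose is drawn uniformly within +/-3 mm and +/-3 degrees
    about the mesh centroid so the implant never sits exactly on the rig
    axes; ten phantom bead positions are scattered around the stem for
    triangulation and rigid-fit checks.
    """
    mesh = make_stem_mesh(seed=seed, n_segments=n_segments)
    cameras, cage, cage_proj = make_stereo_rig(
        angle_deg=angle_deg,
        source_distance_mm=source_distance_mm,
        pixel_spacing=pixel_spacing,
        detector_width_mm=detector_width_mm,
        source_detector_mm=source_detector_mm,
    )
    rng = np.random.default_rng(seed)
    truth = Pose6.from_vector(rng.uniform(-3.0, 3.0, 6), mesh.centroid)
    beads = mesh.centroid + np.column_stack(
        [
            rng.uniform(-30.0, 30.0, 10),
            rng.uniform(-70.0, 70.0, 10),
            rng.uniform(-30.0, 30.0, 10),
        ]
    )
    markers = MarkerSet(tuple(f"m{i}" for i in range(10)), beads, frame="phantom")
    return PhantomScene(
        mesh=mesh,
        ground_truth_pose=truth,
        cameras=cameras,
        cage_markers=cage,
        cage_projections=cage_proj,
        phantom_markers=markers,
        head_center=STEM_HEAD_CENTER.copy(),
        pixel_spacing=pixel_spacing,
        seed=seed,
    )


def simulate_radiograph(
    scene: PhantomScene,
    view: int,
    mode: str = "binary",
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> Radiograph:
    """Virtual radiograph of the implant at the ground-truth pose.

    Binary mode returns the exact silhouette.  Grayscale mode emulates an
    enhanced high-contrast radiograph: foreground ~N(0.95, sigma), background
    ~N(0.2, sigma), clipped to [0, 1].
    """
    cam = scene.cameras[view]
    sil = render_silhouette(scene.mesh, cam, scene.ground_truth_pose)
    if mode == "binary":
        return Radiograph(sil.pixels.astype(np.float64), scene.pixel_spacing, is_binary=True)
    if mode != "grayscale":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    fg = 0.95 + noise_sigma * rng.standard_normal(sil.pixels.shape)
    bg = 0.20 + noise_sigma * rng.standard_normal(sil.pixels.shape)
    img = np.where(sil.pixels > 0, fg, bg)
    return Radiograph(np.clip(img, 0.0, 1.0), scene.pixel_spacing, is_binary=False)


def sample_initial_poses(
    truth: Pose6, bound_mm_deg: float, n: int, seed: int = 0
) -> list[Pose6]:
    """``n`` poses with each DOF offset by an independent Uniform(-b, +b) draw."""
    if bound_mm_deg < 0:
        raise ValueError("bound must be >= 0")
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-bound_mm_deg, bound_mm_deg, size=(n, 6))
    return [
        Pose6.from_vector(truth.as_vector() + off, truth.rotation_center)
        for off in offsets
    ]


# --------------------------------------------------------------------------- #
# drop-out scenarios


def _disk(shape: tuple[int, int], center_xy: np.ndarray, radius: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    return (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius**2


def make_dropout_scenario(
    scene: PhantomScene, fraction: float = 0.15
) -> tuple[list[DropoutMask], list[tuple[np.ndarray, float]]]:
    """Drop-out masks covering ``fraction`` of the lit area around the ball head.

    For each view, a disk anchored on the proximal silhouette boundary of the
    projected (posed) ball head — where an acetabular component would sit —
    is grown until it covers the requested fraction of the silhouette.
    Returns the per-view masks together with matching occluder disks
    ``(center_xy, radius_px)``; each occluder is concentric with its mask
    (so the mask fully discards it) and straddles the implant boundary, so
    burning it into the radiographs with :func:`apply_occluder` corrupts an
    unmasked registration but not a masked one.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    head_world = pose_to_transform(scene.ground_truth_pose).apply(scene.head_center)
    masks: list[DropoutMask] = []
    occluders: list[tuple[np.ndarray, float]] = []
    for cam in scene.cameras:
        sil = render_silhouette(scene.mesh, cam, scene.ground_truth_pose)
        lit = sil.pixels > 0
        target = fraction * lit.sum()
        xy, depth = cam.project_points(head_world.reshape(1, 3))
        head_center = xy[0]
        # anchor on the topmost (most proximal) lit pixel above the head
        # center: the cup occludes the head from the proximal side
        col = int(round(head_center[0]))
        rows = np.nonzero(lit[:, col])[0]
        center = np.array([float(col), float(rows.min())])
        lo, hi = 1.0, float(max(sil.pixels.shape))
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            covered = np.logical_and(_disk(lit.shape, center, mid), lit).sum()
            if covered < target:
                lo = mid
            else:
                hi = mid
        radius = 0.5 * (lo + hi)
        masks.append(DropoutMask(_disk(lit.shape, center, radius)))
        # concentric occluder: fully inside the mask, straddling the boundary
        occluders.append((center.copy(), 0.9 * radius))
    return masks, occluders


def apply_occluder(
    img: Radiograph, center_xy: np.ndarray, radius_px: float, intensity: float = 0.95
) -> Radiograph:
    """Burn a radiopaque disk into a radiograph (1.0 in binary images)."""
    disk = _disk(img.shape, np.asarray(center_xy, dtype=float), radius_px)
    pixels = img.pixels.copy()
    pixels[disk] = 1.0 if img.is_binary else float(np.clip(intensity, 0.0, 1.0))
    return Radiograph(pixels, img.pixel_spacing, is_binary=img.is_binary)


# --------------------------------------------------------------------------- #
# in silico experiment harness


@dataclass
class ExperimentConfig:
    """Protocol of the in silico evaluation.

    Defaults mirror the study conditions: noise-free binary silhouettes,
    90-degree biplanar rig, initial offsets within +/-5 mm and +/-5 degrees,
    the five-stage coarse-to-fine schedule, pixel spacings 0.5 / 0.35 /
    0.143 mm.
    """

    pixel_spacings: tuple[float, ...] = (0.5, 0.35, 0.143)
    initial_error_bounds: tuple[float, ...] = (5.0,)
    trials: int = 20
    seed: int = 1
    mode: str = "binary"
    noise_sigma: float = 0.0
    dropout: bool = False
    dropout_fraction: float = 0.15
    n_segments: int = 96
    angle_deg: float = 90.0
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if any(b < 0 for b in self.initial_error_bounds):
            raise ValueError("bounds must be >= 0")


def margin_for(scene: PhantomScene, bound_mm_deg: float) -> int:
    """ROI margin (px) covering the largest initial silhouette displacement.

    An initial offset of b mm / b degrees can displace a silhouette point by
    up to ``b + lever * sin(b)`` mm in the detector plane (magnified by the
    rig); a 30% headroom is added on top.
    """
    mag = 1.2  # source-detector / source-object distance ratio of the rig
    shift_mm = bound_mm_deg + scene.lever_mm * np.sin(np.deg2rad(bound_mm_deg))
    return max(10, int(np.ceil(1.3 * mag * shift_mm / scene.pixel_spacing)))


_AXES = ("rx", "ry", "rz", "tx", "ty", "tz")


def run_insilico_experiment(config: ExperimentConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the seeded in silico evaluation grid.

    For every (pixel spacing, initial bound) cell, ``config.trials``
    registrations are started from independent random offsets of the
    ground-truth pose and compared against it.  Returns ``(summary, trials)``
    data frames; the summary carries per-axis mean and SD absolute errors,
    mean iteration count, mean relative NOA in percent (binary mode) and the
    number of non-converged trials (which are recorded, never dropped).
    """
    rows = []
    for si, spacing in enumerate(config.pixel_spacings):
        scene = make_scene(
            seed=config.seed,
            pixel_spacing=spacing,
            angle_deg=config.angle_deg,
            n_segments=config.n_segments,
        )
        drs = [
            simulate_radiograph(
                scene, v, mode=config.mode, noise_sigma=config.noise_sigma,
                seed=config.seed + 7919 * v,
            )
            for v in range(2)
        ]
        masks: list[DropoutMask | None] = [None, None]
        if config.dropout:
            dmasks, occluders = make_dropout_scenario(scene, config.dropout_fraction)
            masks = list(dmasks)
            drs = [
                apply_occluder(dr, center, radius)
                for dr, (center, radius) in zip(drs, occluders)
            ]
        truth = scene.ground_truth_pose
        for bi, bound in enumerate(config.initial_error_bounds):
            margin = margin_for(scene, bound)
            views = [
                View(dr, cam, mask)
                for dr, cam, mask in zip(drs, scene.cameras, masks)
            ]
            pose_seed = config.seed + 104729 * si + 1009 * bi + 1
            for trial, pose0 in enumerate(
                sample_initial_poses(truth, bound, config.trials, seed=pose_seed)
            ):
                result = register(
                    views,
                    scene.mesh,
                    pose0,
                    schedule=config.schedule,
                    mode=config.mode,
                    margin_px=margin,
                    threshold=config.threshold,
                )
                err = pose_error(result.pose, truth)
                row = {
                    "spacing": spacing,
                    "bound": bound,
                    "trial": trial,
                    "iterations": result.total_iterations,
                    "relative_noa": result.relative_noa,
                    "converged": result.converged,
                }
                row.update({f"err_{ax}": err[i] for i, ax in enumerate(_AXES)})
                rows.append(row)
    trials_df = pd.DataFrame(rows)
    return summarize_trials(trials_df), trials_df


def summarize_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-trial records into the per-cell summary table."""
    records = []
    for (spacing, bound), cell in trials.groupby(["spacing", "bound"], sort=False):
        rec: dict[str, float] = {"spacing": spacing, "bound": bound}
        for ax in _AXES:
            rec[f"mean_{ax}"] = float(cell[f"err_{ax}"].mean())
            rec[f"sd_{ax}"] = float(cell[f"err_{ax}"].std(ddof=1)) if len(cell) > 1 else 0.0
        rec["mean_iterations"] = float(cell["iterations"].mean())
        rel = cell["relative_noa"].dropna()
        rec["mean_relative_noa_pct"] = float(100.0 * rel.mean()) if len(rel) else float("nan")
        rec["n_trials"] = int(len(cell))
        rec["n_not_converged"] = int((~cell["converged"]).sum())
        records.append(rec)
    return pd.DataFrame(records)
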