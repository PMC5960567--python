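"""Intensity-based nonoverlapping-area (NOA) 2D-3D registration.

The prosthesis pose is recovered by minimizing, over the six pose DOF, the
sum of squared pixel differences between each real radiograph (DR) and a
binary silhouette DRR rendered from the implant mesh:

    PD(p, x, y) = DR(x, y) - DRR(p, x, y)
    NOA(p)      = sum_xy PD(p, x, y)^2

stacked over the anterior-posterior and lateral views.  For binary
segmentations NOA literally counts the pixels on which the two silhouettes
disagree, and the relative form NOA / (NOA + C) — with C the number of
pixels lit in both — is a resolution-independent quality indicator.  For
enhanced grayscale radiographs the same least-squares objective is used with
real-valued residuals.

Optimization is Levenberg-Marquardt with a central-difference Jacobian whose
difference spacing follows a coarse-to-fine schedule (10, 1, 0.1, 0.01,
0.001 mm-or-degrees by default); each stage warm-starts the next.  Since
PD = DR - DRR, the residual derivative is the *negative* central difference
of the rendered silhouettes; the sign constant is fixed here once
(`_JACOBIAN_SIGN`).  Pixels under a user-supplied drop-out mask are removed
from the residual vector entirely, so occluded regions cannot bias the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import GeometryError, Pose6, ProjectionModel
from .imaging import (
    ROI,
    DropoutMask,
    ImagingError,
    Radiograph,
    compute_roi,
    crop,
    threshold_segment,
)
from .renderer import RenderError, Silhouette, TriangleMesh, render_silhouette
from skimage import exposure

__all__ = [
    "DEFAULT_SCHEDULE",
    "View",
    "RegistrationResult",
    "NOAProblem",
    "pixel_differences",
    "noa",
    "relative_noa",
    "lm_stage",
    "register",
]

#: Coarse-to-fine difference spacings, in mm (translations) or degrees
#: (rotations); one schedule covers both because angles are kept in degrees.
DEFAULT_SCHEDULE: tuple[float, ...] = (1e1, 1e0, 1e-1, 1e-2, 1e-3)

# d(PD)/dp = -d(DRR)/dp because PD = DR - DRR and DR does not depend on the
# pose.  Kept as a named constant: flipping it flips the gradient and turns
# the Gauss-Newton step into ascent.
_JACOBIAN_SIGN: float = -1.0


def validate_schedule(schedule: Sequence[float]) -> tuple[float, ...]:
    s = tuple(float(e) for e in schedule)
    if not s or any(e <= 0 for e in s):
        raise ValueError("schedule must contain positive spacings")
    if any(b >= a for a, b in zip(s, s[1:])):
        raise ValueError("schedule must be strictly decreasing")
    return s


@dataclass(frozen=True)
class View:
    """One calibrated radiographic view: image, camera, optional drop-out mask."""

    radiograph: Radiograph
    camera: ProjectionModel
    mask: DropoutMask | None = None


@dataclass
class RegistrationResult:
    """Outcome of a multi-stage NOA registration."""

    pose: Pose6
    stage_iterations: list[int]
    noa: float
    relative_noa: float | None  # only defined when both DR views are binary
    converged: bool
    stage_residuals: list[float] = field(default_factory=list)

    @property
    def total_iterations(self) -> int:
        return int(sum(self.stage_iterations))


# --------------------------------------------------------------------------- #
# residuals and metric


def _as_pixels(drr: Silhouette | np.ndarray) -> np.ndarray:
    return drr.pixels if isinstance(drr, Silhouette) else np.asarray(drr)


def pixel_differences(
    dr: Radiograph,
    drr: Silhouette | np.ndarray,
    roi: ROI | None = None,
    mask: DropoutMask | None = None,
) -> np.ndarray:
    """Residual vector DR - DRR over the unmasked ROI pixels, row-major.

    ``drr`` must be a full-frame silhouette matching the radiograph shape.
    Masked pixels are omitted (the vector shrinks accordingly).
    """
    d = _as_pixels(drr).astype(np.float64)
    if d.shape != dr.shape:
        raise ImagingError(f"DR {dr.shape} and DRR {d.shape} dimensions differ")
    if isinstance(drr, Silhouette) and abs(drr.pixel_spacing - dr.pixel_spacing) > 1e-9:
        raise ImagingError("DR and DRR pixel spacings differ")
    a = dr.pixels
    if roi is not None:
        a, d = crop(a, roi), crop(d, roi)
    keep = np.ones(a.shape, dtype=bool)
    if mask is not None:
        m = mask.pixels
        if m.shape != dr.shape:
            raise ImagingError("mask dimensions do not match the radiograph")
        keep = ~(crop(m, roi) if roi is not None else m)
    return (a - d)[keep]


def noa(residual: np.ndarray) -> float:
    """Nonoverlapping-area objective: sum of squared residual entries."""
    r = np.asarray(residual, dtype=np.float64)
    return float(r @ r)


def relative_noa(
    dr: Radiograph,
    drr: Silhouette | np.ndarray,
    roi: ROI | None = None,
    mask: DropoutMask | None = None,
) -> float:
    """Relative nonoverlapping area NOA / (NOA + C), in [0, 1].

    C counts the unmasked pixels lit in both the radiographic segmentation
    and the DRR.  Defined for binary radiographs only.
    """
    if not dr.is_binary:
        raise ImagingError("relative NOA is undefined for grayscale radiographs")
    res = pixel_differences(dr, drr, roi, mask)
    size = noa(res)
    a = dr.pixels
    d = _as_pixels(drr)
    if roi is not None:
        a, d = crop(a, roi), crop(d, roi)
    both = (a == 1) & (d == 1)
    if mask is not None:
        m = crop(mask.pixels, roi) if roi is not None else mask.pixels
        both = both & ~m
    denom = size + float(both.sum())
    return 0.0 if denom == 0 else size / denom


# --------------------------------------------------------------------------- #
# the stacked two-view problem


class NOAProblem:
    """Precomputed residual/Jacobian machinery for one registration.

    The ROI of each view is derived once from the radiographic segmentation
    (re-deriving it per iteration would change the objective mid-run) and all
    residuals and Jacobian columns are evaluated on the fixed ROI crops, with
    drop-out pixels removed.  In grayscale mode the radiograph is
    histogram-equalized within its ROI crop, so the implant occupies the top
    of the local intensity range regardless of how much background the full
    frame contains.
    """

    def __init__(
        self,
        mesh: TriangleMesh,
        views: Sequence[View],
        mode: str = "binary",
        margin_px: int = 20,
        threshold: float = 0.5,
    ) -> None:
        if mode not in ("binary", "grayscale"):
            raise ValueError(f"unknown mode {mode!r}")
        if len(views) < 1:
            raise ValueError("at least one calibrated view is required")
        self.mesh = mesh
        self.mode = mode
        self.views = list(views)
        self._cams: list[ProjectionModel] = []
        self._rois: list[ROI] = []
        self._dr: list[np.ndarray] = []
        self._keep: list[np.ndarray] = []
        for view in self.views:
            dr, cam = view.radiograph, view.camera
            if dr.shape != (cam.image_height, cam.image_width):
                raise ImagingError("radiograph dimensions do not match the camera")
            if abs(dr.pixel_spacing - cam.pixel_spacing) > 1e-9:
                raise ImagingError("radiograph and camera pixel spacings differ")
            if mode == "binary":
                if not dr.is_binary:
                    raise ImagingError("binary mode requires binary segmentations")
                seg = dr
            else:
                if dr.is_binary:
                    raise ImagingError("grayscale mode requires a grayscale radiograph")
                seg = threshold_segment(dr, threshold)
            roi = compute_roi(seg, margin_px)
            dr_roi = crop(dr.pixels, roi).astype(np.float64)
            if mode == "grayscale":
                dr_roi = np.clip(exposure.equalize_hist(dr_roi, nbins=256), 0.0, 1.0)
            keep = np.ones(dr_roi.shape, dtype=bool)
            if view.mask is not None:
                if view.mask.pixels.shape != dr.shape:
                    raise ImagingError("mask dimensions do not match the radiograph")
                keep = ~crop(view.mask.pixels, roi)
            self._cams.append(cam)
            self._rois.append(roi)
            self._dr.append(dr_roi)
            self._keep.append(keep)
        self.n_residuals = int(sum(k.sum() for k in self._keep))

    @property
    def rois(self) -> list[ROI]:
        return list(self._rois)

    def render(self, pose: Pose6) -> list[np.ndarray]:
        """ROI-cropped binary DRRs of all views at ``pose``."""
        return [
            render_silhouette(self.mesh, cam, pose, roi=roi).pixels
            for cam, roi in zip(self._cams, self._rois)
        ]

    def residual(self, pose: Pose6, drrs: list[np.ndarray] | None = None) -> np.ndarray:
        """Stacked residual vector (AP first, then LAT; row-major per ROI)."""
        if drrs is None:
            drrs = self.render(pose)
        parts = [
            (dr - drr)[keep]
            for dr, drr, keep in zip(self._dr, drrs, self._keep)
        ]
        return np.concatenate(parts)

    def noa(self, pose: Pose6) -> float:
        return noa(self.residual(pose))

    def relative_noa(self, pose: Pose6) -> float:
        """Relative NOA at ``pose`` over the unmasked ROI pixels (binary mode)."""
        if self.mode != "binary":
            raise ImagingError("relative NOA is undefined for grayscale registrations")
        size = 0.0
        overlap = 0.0
        for dr, drr, keep in zip(self._dr, self.render(pose), self._keep):
            diff = (dr - drr)[keep]
            size += float(diff @ diff)
            overlap += float(((dr == 1) & (drr == 1) & keep).sum())
        denom = size + overlap
        return 0.0 if denom == 0 else size / denom

    def jacobian(self, pose: Pose6, eps: float) -> np.ndarray:
        """Central-difference Jacobian of the residual vector.

        One column per DOF in the order (rx, ry, rz, tx, ty, tz); rotations
        are perturbed by ``eps`` degrees, translations by ``eps`` mm.  Each
        column costs exactly two silhouette renders per view.
        """
        if eps <= 0:
            raise ValueError("difference spacing must be positive")
        jac = np.empty((self.n_residuals, 6), dtype=np.float64)
        scale = _JACOBIAN_SIGN / (2.0 * eps)
        for dof in range(6):
            plus = self.render(pose.perturbed(dof, +eps))
            minus = self.render(pose.perturbed(dof, -eps))
            col = [
                (p.astype(np.float64) - m)[keep]
                for p, m, keep in zip(plus, minus, self._keep)
            ]
            jac[:, dof] = scale * np.concatenate(col)
        return jac


# --------------------------------------------------------------------------- #
# Levenberg-Marquardt


def lm_stage(
    problem: NOAProblem,
    pose0: Pose6,
    eps: float,
    max_iterations: int = 100,
    rel_reduction_tol: float = 1e-6,
) -> tuple[Pose6, int, float, bool]:
    """One Levenberg-Marquardt stage at difference spacing ``eps``.

    Damped Gauss-Newton on the stacked residual with a monotone acceptance
    rule: a step is taken only if it strictly reduces the objective, so the
    returned pose never has a larger residual than the start.  The stage
    stops when the relative residual reduction falls below
    ``rel_reduction_tol``, the proposed step norm falls below ``eps / 10``,
    damping saturates, or ``max_iterations`` Jacobian evaluations are spent.

    Returns ``(pose, iterations, final_ssr, converged)``.
    """
    pose = pose0
    r = problem.residual(pose)
    ssr = float(r @ r)
    if ssr == 0.0:
        return pose, 0, 0.0, True
    lam: float | None = None
    iterations = 0
    converged = True
    while iterations < max_iterations:
        iterations += 1
        jac = problem.jacobian(pose, eps)
        jtj = jac.T @ jac
        trace = float(np.trace(jtj))
        if trace == 0.0:
            # objective locally flat at +-eps in every DOF; nothing to gain
            iterations -= 1
            break
        if lam is None:
            lam = 1e-3
        # Marquardt scaling: damp each DOF relative to its own curvature so
        # weakly observed axes (proximodistal rotation) are not frozen out
        damp = np.diag(np.maximum(np.diag(jtj), 1e-12 * trace))
        g = jac.T @ r
        accepted = False
        exhausted = False
        while not accepted:
            try:
                delta = np.linalg.solve(jtj + lam * damp, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            if float(np.linalg.norm(delta)) < eps / 10.0:
                exhausted = True  # step resolution finer than this stage resolves
                break
            candidate = Pose6.from_vector(pose.as_vector() + delta, pose.rotation_center)
            try:
                r_new = problem.residual(candidate)
            except (RenderError, GeometryError):
                lam *= 10.0  # stepped out of the renderable domain
                if lam > 1e12:
                    exhausted = True
                    break
                continue
            ssr_new = float(r_new @ r_new)
            if ssr_new < ssr:
                accepted = True
                rel_reduction = (ssr - ssr_new) / ssr
                pose, r, ssr = candidate, r_new, ssr_new
                lam = max(lam / 10.0, 1e-15)
            else:
                lam *= 10.0
                if lam > 1e12:
                    exhausted = True
                    break
        if exhausted or not accepted:
            break
        if ssr == 0.0 or rel_reduction < rel_reduction_tol:
            break
    else:
        converged = False  # budget hit while still improving
    return pose, iterations, ssr, converged


def register(
    views: Sequence[View],
    mesh: TriangleMesh,
    pose0: Pose6,
    schedule: Sequence[float] = DEFAULT_SCHEDULE,
    mode: str = "binary",
    margin_px: int = 20,
    threshold: float = 0.5,
    max_iterations_per_stage: int = 100,
) -> RegistrationResult:
    """Full coarse-to-fine NOA registration of a mesh into calibrated views.

    Runs one LM stage per schedule entry, warm-starting each from the
    previous stage's pose.  ``margin_px`` enlarges the ROI derived from the
    radiographic segmentation and must exceed the largest silhouette
    displacement the initial pose error can cause, otherwise discordant
    pixels fall outside the metric.
    """
    sched = validate_schedule(schedule)
    problem = NOAProblem(mesh, views, mode=mode, margin_px=margin_px, threshold=threshold)
    pose = Pose6.from_vector(pose0.as_vector(), pose0.rotation_center)
    stage_iterations: list[int] = []
    stage_residuals: list[float] = []
    converged = True
    ssr = problem.noa(pose)
    for eps in sched:
        pose, iters, ssr, ok = lm_stage(
            problem, pose, eps, max_iterations=max_iterations_per_stage
        )
        stage_iterations.append(iters)
        stage_residuals.append(ssr)
        converged = converged and ok
    rel = problem.relative_noa(pose) if mode == "binary" else None
    return RegistrationResult(
        pose=pose,
        stage_iterations=stage_iterations,
        noa=ssr,
        relative_noa=rel,
        converged=converged,
        stage_residuals=stage_residuals,
    )
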