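"""Binary silhouette rendering of triangle meshes through a DLT camera.

The digitally reconstructed radiograph used by the registration is a binary
silhouette: a pixel is lit iff its center falls inside the 2D projection of at
least one posed triangle.  Because the silhouette is the union (pixel-wise OR)
of the projected triangles, no depth buffer is needed and back-face culling is
deliberately disabled.  The fill rule is inclusive: a pixel center exactly on
a triangle edge counts as inside, which makes the union seam-free and the
result deterministic.

The rasterizer is a software edge-function scanner over per-triangle bounding
boxes, compiled with numba for throughput; its semantics are identical to a
brute-force point-in-triangle test at every pixel center (the test suite
checks this equivalence).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from numba import njit

from .geometry import Pose6, ProjectionModel, RigidTransform, pose_to_transform

__all__ = ["TriangleMesh", "Silhouette", "load_mesh", "save_mesh", "render_silhouette"]


class RenderError(ValueError):
    """Unrenderable input (mesh behind the source, bad mesh file, ...)."""


@dataclass(frozen=True)
class TriangleMesh:
    """Implant surface: vertices in mm and triangle vertex indices."""

    vertices: np.ndarray  # (N, 3) float
    faces: np.ndarray  # (M, 3) int

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(self.vertices, dtype=np.float64)
        f = np.ascontiguousarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3 or len(v) == 0:
            raise RenderError("vertices must be a non-empty (N, 3) array")
        if f.ndim != 2 or f.shape[1] != 3 or len(f) == 0:
            raise RenderError("faces must be a non-empty (M, 3) array")
        if not np.all(np.isfinite(v)):
            raise RenderError("vertex coordinates must be finite")
        if f.min() < 0 or f.max() >= len(v):
            raise RenderError("face indices out of range")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def centroid(self) -> np.ndarray:
        """Mean vertex position (default rotation center for registration)."""
        return self.vertices.mean(axis=0)

    def transformed(self, transform: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(transform.apply(self.vertices), self.faces)

    def posed(self, pose: Pose6) -> "TriangleMesh":
        return self.transformed(pose_to_transform(pose))


@dataclass
class Silhouette:
    """Binary DRR grid. ``origin`` is the full-frame pixel index of element
    (0, 0), nonzero when only a region of interest was rendered."""

    pixels: np.ndarray  # (H, W) uint8 in {0, 1}
    pixel_spacing: float
    origin: tuple[int, int] = (0, 0)  # (x0, y0)

    @property
    def lit_count(self) -> int:
        return int(self.pixels.sum())


def load_mesh(path: str | Path) -> TriangleMesh:
    """Load an STL/PLY/OBJ surface mesh (coordinates in mm)."""
    try:
        m = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise RenderError(f"cannot read mesh {path!r}: {exc}") from exc
    if not hasattr(m, "vertices") or len(m.vertices) == 0 or len(m.faces) == 0:
        raise RenderError(f"mesh {path!r} is empty")
    return TriangleMesh(np.asarray(m.vertices), np.asarray(m.faces))


def save_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    trimesh.Trimesh(mesh.vertices, mesh.faces, process=False).export(str(path))


@njit(cache=False)
def _rasterize(xy, faces, out):  # pragma: no cover - exercised via render_silhouette
    h, w = out.shape
    for t in range(faces.shape[0]):
        ax, ay = xy[faces[t, 0], 0], xy[faces[t, 0], 1]
        bx, by = xy[faces[t, 1], 0], xy[faces[t, 1], 1]
        cx, cy = xy[faces[t, 2], 0], xy[faces[t, 2], 1]
        area = (bx - ax) * (cy - ay) - (cx - ax) * (by - ay)
        if area == 0.0:
            continue  # degenerate projection contributes no pixels
        s = 1.0 if area > 0.0 else -1.0
        lo_x = min(ax, min(bx, cx))
        hi_x = max(ax, max(bx, cx))
        lo_y = min(ay, min(by, cy))
        hi_y = max(ay, max(by, cy))
        x0 = int(np.ceil(lo_x))
        x1 = int(np.floor(hi_x))
        y0 = int(np.ceil(lo_y))
        y1 = int(np.floor(hi_y))
        if x0 < 0:
            x0 = 0
        if y0 < 0:
            y0 = 0
        if x1 > w - 1:
            x1 = w - 1
        if y1 > h - 1:
            y1 = h - 1
        for py in range(y0, y1 + 1):
            fy = float(py)
            for px in range(x0, x1 + 1):
                fx = float(px)
                if s * ((bx - ax) * (fy - ay) - (by - ay) * (fx - ax)) < 0.0:
                    continue
                if s * ((cx - bx) * (fy - by) - (cy - by) * (fx - bx)) < 0.0:
                    continue
                if s * ((ax - cx) * (fy - cy) - (ay - cy) * (fx - cx)) < 0.0:
                    continue
                out[py, px] = 1


def render_silhouette(
    mesh: TriangleMesh,
    camera: ProjectionModel,
    pose: Pose6 | None = None,
    roi=None,
) -> Silhouette:
    """Rasterize the binary silhouette of ``mesh`` at ``pose`` through ``camera``.

    ``roi`` (any object with ``x0, y0, width, height``) restricts rendering to
    a crop of the full frame; the returned silhouette then has that shape and
    carries the crop offset in ``origin``.  Raises :class:`RenderError` if any
    posed vertex has non-positive projective depth (clipping is unsupported).
    """
    posed = mesh.posed(pose) if pose is not None else mesh
    xy, depth = camera.project_points(posed.vertices)
    if np.any(depth <= 0):
        raise RenderError("posed mesh has vertices at non-positive depth")
    if roi is None:
        x0, y0 = 0, 0
        h, w = camera.image_height, camera.image_width
    else:
        x0, y0 = int(roi.x0), int(roi.y0)
        h, w = int(roi.height), int(roi.width)
    pts = np.ascontiguousarray(xy - np.array([x0, y0], dtype=float))
    out = np.zeros((h, w), dtype=np.uint8)
    _rasterize(pts, posed.faces, out)
    return Silhouette(out, camera.pixel_spacing, origin=(x0, y0))
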