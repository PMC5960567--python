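"""Serialization shared by the CLI and the experiment harness.

JSON for structured artifacts (poses, calibrations, result records), CSV for
marker lists and experiment tables, plain image files for rasters.  Every
JSON document is self-describing: it carries ``schema_version`` and ``kind``
and is rejected loudly on a mismatch rather than silently misparsed.  Floats
survive a round trip losslessly (JSON shortest-repr is exact for doubles).
Angles are always degrees and lengths always millimetres.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .geometry import GeometryError, MarkerSet, Pose6, ProjectionModel
from .registration import RegistrationResult

__all__ = [
    "SchemaError",
    "SCHEMA_VERSION",
    "save_pose",
    "load_pose",
    "save_calibration",
    "load_calibration",
    "save_result_record",
    "load_result_record",
    "load_markers_csv",
    "save_markers_csv",
    "load_image_points_csv",
    "file_sha256",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Malformed or wrong-version document."""


def _check_header(doc: dict, kind: str, path: str | Path) -> None:
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: schema_version {version!r} is not supported (expected {SCHEMA_VERSION})"
        )
    if doc.get("kind") != kind:
        raise SchemaError(f"{path}: kind {doc.get('kind')!r}, expected {kind!r}")


def _read_json(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            return json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: malformed JSON ({exc})") from exc


def _write_json(doc: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------- #
# poses


def pose_to_dict(pose: Pose6) -> dict:
    return {
        "rx_deg": pose.rx,
        "ry_deg": pose.ry,
        "rz_deg": pose.rz,
        "tx_mm": pose.tx,
        "ty_mm": pose.ty,
        "tz_mm": pose.tz,
        "rotation_center_mm": list(pose.rotation_center),
    }


def pose_from_dict(d: dict, path: str | Path = "<pose>") -> Pose6:
    try:
        return Pose6(
            rx=float(d["rx_deg"]),
            ry=float(d["ry_deg"]),
            rz=float(d["rz_deg"]),
            tx=float(d["tx_mm"]),
            ty=float(d["ty_mm"]),
            tz=float(d["tz_mm"]),
            rotation_center=np.asarray(d["rotation_center_mm"], dtype=float),
        )
    except KeyError as exc:
        raise SchemaError(f"{path}: missing pose field {exc.args[0]!r}") from exc


def save_pose(pose: Pose6, path: str | Path) -> None:
    _write_json(
        {"schema_version": SCHEMA_VERSION, "kind": "pose", **pose_to_dict(pose)}, path
    )


def load_pose(path: str | Path) -> Pose6:
    doc = _read_json(path)
    _check_header(doc, "pose", path)
    return pose_from_dict(doc, path)


# --------------------------------------------------------------------------- #
# calibrations


def save_calibration(views: dict[str, ProjectionModel], path: str | Path) -> None:
    """Write a multi-view calibration (keys are view names, e.g. ap/lat)."""
    doc: dict[str, Any] = {"schema_version": SCHEMA_VERSION, "kind": "calibration", "views": {}}
    for name, cam in views.items():
        doc["views"][name] = {
            "matrix_row_major": [float(v) for v in cam.matrix.ravel()],
            "image_width_px": cam.image_width,
            "image_height_px": cam.image_height,
            "pixel_spacing_mm": cam.pixel_spacing,
        }
    _write_json(doc, path)


def load_calibration(path: str | Path) -> dict[str, ProjectionModel]:
    doc = _read_json(path)
    _check_header(doc, "calibration", path)
    views = doc.get("views")
    if not isinstance(views, dict) or not views:
        raise SchemaError(f"{path}: missing or empty 'views'")
    out: dict[str, ProjectionModel] = {}
    for name, v in views.items():
        try:
            matrix = np.asarray(v["matrix_row_major"], dtype=float).reshape(3, 4)
            out[name] = ProjectionModel(
                matrix,
                int(v["image_width_px"]),
                int(v["image_height_px"]),
                float(v["pixel_spacing_mm"]),
            )
        except KeyError as exc:
            raise SchemaError(
                f"{path}: view {name!r} is missing field {exc.args[0]!r}"
            ) from exc
        except (ValueError, GeometryError) as exc:
            raise SchemaError(f"{path}: view {name!r}: {exc}") from exc
    return out


# --------------------------------------------------------------------------- #
# registration result records


def save_result_record(
    result: RegistrationResult,
    path: str | Path,
    inputs: dict[str, str] | None = None,
    config: dict | None = None,
    wall_time_s: float | None = None,
) -> None:
    """Persist a registration outcome with input checksums and config echo."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": "result",
        "inputs_sha256": inputs or {},
        "config": config or {},
        "pose": pose_to_dict(result.pose),
        "stage_iterations": list(result.stage_iterations),
        "total_iterations": result.total_iterations,
        "noa": result.noa,
        "relative_noa": result.relative_noa,
        "relative_noa_pct": None if result.relative_noa is None else 100.0 * result.relative_noa,
        "converged": result.converged,
        "stage_residuals": list(result.stage_residuals),
        "wall_time_s": wall_time_s,
    }
    _write_json(doc, path)


def load_result_record(path: str | Path) -> dict:
    doc = _read_json(path)
    _check_header(doc, "result", path)
    doc["pose"] = pose_from_dict(doc["pose"], path)
    return doc


# --------------------------------------------------------------------------- #
# marker CSV files: columns label, x, y[, z]


def save_markers_csv(markers: MarkerSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": markers.labels,
            "x": markers.points[:, 0],
            "y": markers.points[:, 1],
            "z": markers.points[:, 2],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def load_markers_csv(path: str | Path, frame: str = "world") -> MarkerSet:
    df = pd.read_csv(path)
    for col in ("label", "x", "y", "z"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return MarkerSet(
        tuple(str(l) for l in df["label"]),
        df[["x", "y", "z"]].to_numpy(dtype=float),
        frame=frame,
    )


def load_image_points_csv(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    """2D image-point CSV (label, x, y) -> labels and an (N, 2) pixel array."""
    df = pd.read_csv(path)
    for col in ("label", "x", "y"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return tuple(str(l) for l in df["label"]), df[["x", "y"]].to_numpy(dtype=float)
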