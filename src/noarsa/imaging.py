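"""Radiograph handling: I/O, enhancement, segmentation, ROIs, drop-out masks.

Radiographs are kept as float grids in [0, 1] with a physical pixel spacing.
Enhancement is plain histogram equalization (a monotone CDF remapping), after
which a highly radiopaque implant occupies the top of the intensity range and
a fixed threshold separates it from the background.  Drop-out masks mark
image regions the user wants excluded from the registration metric, e.g.
where an acetabular component occludes the ball head.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage import exposure

__all__ = [
    "ImagingError",
    "Radiograph",
    "DropoutMask",
    "ROI",
    "equalize_histogram",
    "gamma_correct",
    "threshold_segment",
    "compute_roi",
    "load_radiograph",
    "save_radiograph",
    "load_mask",
    "save_mask",
    "crop",
]


class ImagingError(ValueError):
    """Invalid image input (range, dimensions, empty segmentation, ...)."""


@dataclass
class Radiograph:
    """Pixel grid with intensities in [0, 1] and spacing in mm/px."""

    pixels: np.ndarray  # (H, W) float64
    pixel_spacing: float
    is_binary: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise ImagingError("radiograph must be a 2D grid")
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ImagingError("intensities must lie in [0, 1]")
        if self.is_binary and p.size and not np.all((p == 0) | (p == 1)):
            raise ImagingError("binary radiograph contains non-{0,1} values")
        if self.pixel_spacing <= 0:
            raise ImagingError("pixel spacing must be positive")
        self.pixels = p

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class DropoutMask:
    """Boolean grid; True marks pixels excluded from the registration."""

    pixels: np.ndarray  # (H, W) bool

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ImagingError("mask must be a 2D grid")


@dataclass(frozen=True)
class ROI:
    """Axis-aligned crop rectangle in pixels, recorded with its margin."""

    x0: int
    y0: int
    width: int
    height: int
    margin: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.margin < 0:
            raise ImagingError("ROI must have positive size and margin >= 0")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width))


def equalize_histogram(img: Radiograph, nbins: int = 256) -> Radiograph:
    """Histogram-equalize a grayscale radiograph (CDF mapping onto [0, 1]).

    The mapping is monotone non-decreasing, so pixel ordering is preserved.
    Binary images are rejected: there is nothing to equalize and the
    registration uses them directly.
    """
    if img.is_binary:
        raise ImagingError("histogram equalization is undefined for binary images")
    eq = exposure.equalize_hist(img.pixels, nbins=nbins)
    return Radiograph(np.clip(eq, 0.0, 1.0), img.pixel_spacing, is_binary=False)


def gamma_correct(img: Radiograph, gamma: float) -> Radiograph:
    """Optional intensity-curve adjustment ``v -> v**gamma`` (gamma > 0)."""
    if img.is_binary:
        raise ImagingError("gamma correction is undefined for binary images")
    if gamma <= 0:
        raise ImagingError("gamma must be positive")
    return Radiograph(np.power(img.pixels, gamma), img.pixel_spacing)


def threshold_segment(img: Radiograph, threshold: float = 0.5) -> Radiograph:
    """Binarize: pixel >= threshold -> 1 else 0 (threshold as fraction of range)."""
    if not 0.0 < threshold < 1.0:
        raise ImagingError("threshold must lie in (0, 1)")
    seg = (img.pixels >= threshold).astype(np.float64)
    return Radiograph(seg, img.pixel_spacing, is_binary=True)


def compute_roi(seg: Radiograph | np.ndarray, margin_px: int) -> ROI:
    """Tight bounding box of the lit pixels, enlarged by ``margin_px`` and
    clamped to the image bounds."""
    pixels = seg.pixels if isinstance(seg, Radiograph) else np.asarray(seg)
    ys, xs = np.nonzero(pixels)
    if len(ys) == 0:
        raise ImagingError("empty segmentation: cannot derive an ROI")
    if margin_px < 0:
        raise ImagingError("margin must be >= 0")
    h, w = pixels.shape
    x0 = max(0, int(xs.min()) - margin_px)
    y0 = max(0, int(ys.min()) - margin_px)
    x1 = min(w - 1, int(xs.max()) + margin_px)
    y1 = min(h - 1, int(ys.max()) + margin_px)
    return ROI(x0, y0, x1 - x0 + 1, y1 - y0 + 1, margin=margin_px)


def crop(grid: np.ndarray, roi: ROI) -> np.ndarray:
    """Crop a 2D array to an ROI (shape-checked)."""
    a = np.asarray(grid)
    if a.ndim != 2:
        raise ImagingError("can only crop 2D grids")
    ys, xs = roi.slices
    if roi.y0 + roi.height > a.shape[0] or roi.x0 + roi.width > a.shape[1]:
        raise ImagingError("ROI exceeds image bounds")
    return a[ys, xs]


# --------------------------------------------------------------------------- #
# file I/O — 8/16-bit PNG and TIFF, normalized to [0, 1] on load


def load_radiograph(path: str | Path, pixel_spacing: float, binary: bool = False) -> Radiograph:
    data = iio.imread(str(path))
    src_dtype = data.dtype
    if data.ndim == 3:  # collapse RGB(A) to luminance
        data = data[..., :3].mean(axis=2)
    raw = data.astype(np.float64)
    if np.issubdtype(src_dtype, np.integer):
        raw = raw / float(np.iinfo(src_dtype).max)
    elif raw.size and raw.max() > 1.0:
        raw = raw / raw.max()
    if binary:
        raw = (raw >= 0.5).astype(np.float64)
    return Radiograph(raw, pixel_spacing, is_binary=binary)


def save_radiograph(img: Radiograph, path: str | Path) -> None:
    """Write as 8-bit PNG/TIFF (binary images as 0/255)."""
    data = np.round(img.pixels * 255.0).astype(np.uint8)
    iio.imwrite(str(path), data)


def load_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> DropoutMask:
    """Read a drop-out mask image; any nonzero pixel is excluded."""
    raw = iio.imread(str(path))
    if raw.ndim == 3:
        raw = raw[..., :3].max(axis=2)
    mask = DropoutMask(raw != 0)
    if expected_shape is not None and mask.pixels.shape != tuple(expected_shape):
        raise ImagingError(
            f"mask shape {mask.pixels.shape} does not match image {tuple(expected_shape)}"
        )
    return mask


def save_mask(mask: DropoutMask, path: str | Path) -> None:
    iio.imwrite(str(path), (mask.pixels.astype(np.uint8) * 255))
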