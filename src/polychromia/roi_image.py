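"""Image and ROI loading, channel decomposition, grayscale/composite conversion.

The unit of analysis is an 8-bit RGB photograph of a pigmented skin lesion
with two regions of interest: a *lesional* ROI covering the lesion and a
*perilesional* ROI on adjacent clinically normal skin, which serves as an
internal baseline for illumination and device effects.

Conversion conventions are explicit and configurable because published
histogram tools differ in their grayscale dialect:

* ``unweighted_mean`` (default): per-pixel ``(R+G+B)/3``, round-half-up.
  This is also the composite "RGB histogram" plane, which makes composite
  and grayscale entropies identical by construction — the mechanism behind
  near-equal global grayscale/RGB entropies on any image.
* ``itu601_weighted``: ITU-R BT.601 luma, ``0.299 R + 0.587 G + 0.114 B``,
  round-half-up.

Coordinates are 0-based and row-major.  Polygon ROIs are filled with the
even-odd rule; a pixel belongs to the ROI when its center lies inside the
closed polygon (boundary centers included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import imageio.v3 as iio
import numpy as np

from .exceptions import (
    EmptyROIError,
    FormatError,
    ShapeMismatchError,
    UnsupportedDepthError,
)

logger = logging.getLogger("polychromia")

#: ITU-R BT.601 luma weights (sum to 1 exactly).
ITU601_WEIGHTS = (0.299, 0.587, 0.114)

GRAYSCALE_MODES = ("unweighted_mean", "itu601_weighted")
ROI_LABELS = ("lesional", "perilesional")

PolygonSpec = Sequence[Sequence[float]]
MaskSpec = Union[str, Path, PolygonSpec]


@dataclass(frozen=True)
class RGBImage:
    """Three aligned 8-bit channel planes.

    Each plane is a ``(height, width)`` ``uint8`` array.
    """

    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.red.shape, self.green.shape, self.blue.shape}
        if len(shapes) != 1 or self.red.ndim != 2:
            raise ShapeMismatchError(
                f"channel planes must share one 2-D shape, got "
                f"{self.red.shape}, {self.green.shape}, {self.blue.shape}"
            )
        for name, plane in (("red", self.red), ("green", self.green), ("blue", self.blue)):
            if plane.dtype != np.uint8:
                raise UnsupportedDepthError(
                    f"{name} plane has dtype {plane.dtype}; 8-bit (uint8) required"
                )

    @property
    def height(self) -> int:
        return self.red.shape[0]

    @property
    def width(self) -> int:
        return self.red.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.red.shape

    def channel(self, name: str) -> np.ndarray:
        return {"red": self.red, "green": self.green, "blue": self.blue}[name]

    def to_array(self) -> np.ndarray:
        """Recombine the channels into an ``(H, W, 3)`` array (lossless)."""
        return np.stack([self.red, self.green, self.blue], axis=-1)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "RGBImage":
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise FormatError(f"expected (H, W, >=3) array, got shape {arr.shape}")
        return cls(
            red=np.ascontiguousarray(arr[..., 0]),
            green=np.ascontiguousarray(arr[..., 1]),
            blue=np.ascontiguousarray(arr[..., 2]),
        )


@dataclass(frozen=True)
class ROIMask:
    """Boolean plane selecting lesional or perilesional pixels."""

    selected: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}, got {self.label!r}")
        if self.selected.dtype != bool or self.selected.ndim != 2:
            raise ShapeMismatchError("mask must be a 2-D boolean plane")
        if not self.selected.any():
            raise EmptyROIError(f"{self.label} ROI selects no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.selected.sum())


def load_rgb_image(path: Union[str, Path]) -> RGBImage:
    """Load an 8-bit RGB image (PNG/TIFF/JPEG).

    A fourth (alpha) channel is dropped with a logged warning.  Images that
    are not 8-bit per channel raise :class:`UnsupportedDepthError`; files
    that do not decode to an image with at least three channels raise
    :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises plugin-specific errors
        raise FormatError(f"could not decode {path} as an image: {exc}") from exc
    if arr.dtype != np.uint8:
        raise UnsupportedDepthError(
            f"{path}: bit depth {arr.dtype} unsupported; 8 bits per channel required"
        )
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(
            f"{path}: expected >=3 channels, got shape {arr.shape}"
        )
    if arr.shape[2] > 3:
        logger.warning("%s: alpha channel present; dropping it", path)
        arr = arr[..., :3]
    return RGBImage.from_array(arr)


def _polygon_mask(vertices: PolygonSpec, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon with the even-odd rule on pixel centers.

    Vertices are ``(x, y)`` in 0-based pixel coordinates; pixel ``(row, col)``
    has its center at ``(x=col, y=row)``.  Centers lying exactly on an edge
    are included (closed region).
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise FormatError("polygon needs >=3 (x, y) vertices")
    height, width = shape
    mask = np.zeros(shape, dtype=bool)

    x0 = max(int(np.floor(verts[:, 0].min())), 0)
    x1 = min(int(np.ceil(verts[:, 0].max())), width - 1)
    y0 = max(int(np.floor(verts[:, 1].min())), 0)
    y1 = min(int(np.ceil(verts[:, 1].max())), height - 1)
    if x1 < x0 or y1 < y0:
        return mask

    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    px = xs.ravel().astype(float)
    py = ys.ravel().astype(float)

    inside = np.zeros(px.shape, dtype=bool)   # even-odd crossing parity
    on_edge = np.zeros(px.shape, dtype=bool)

    closed = np.vstack([verts, verts[:1]])
    for (ax, ay), (bx, by) in zip(closed[:-1], closed[1:]):
        # exact on-segment test
        cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
        within = (
            (np.minimum(ax, bx) - 1e-9 <= px) & (px <= np.maximum(ax, bx) + 1e-9)
            & (np.minimum(ay, by) - 1e-9 <= py) & (py <= np.maximum(ay, by) + 1e-9)
        )
        on_edge |= (np.abs(cross) < 1e-9) & within
        # ray cast toward +x; half-open in y avoids double-counting vertices
        if ay != by:
            cond = ((ay <= py) & (py < by)) | ((by <= py) & (py < ay))
            x_int = ax + (py - ay) * (bx - ax) / (by - ay)
            inside ^= cond & (x_int > px)

    mask[py[inside | on_edge].astype(int), px[inside | on_edge].astype(int)] = True
    return mask


def load_mask(spec: MaskSpec, image_shape: tuple[int, int], label: str) -> ROIMask:
    """Build an :class:`ROIMask` from a mask-image path or a polygon.

    Mask images must be single-channel; pixels greater than zero are
    selected.  Polygons are sequences of ``(x, y)`` vertices, filled per the
    module's even-odd convention.
    """
    if isinstance(spec, (str, Path)):
        path = Path(spec)
        if not path.exists():
            raise FormatError(f"mask file not found: {path}")
        try:
            arr = iio.imread(path)
        except Exception as exc:
            raise FormatError(f"could not decode mask {path}: {exc}") from exc
        if arr.ndim != 2:
            raise FormatError(
                f"mask {path} must be single-channel, got shape {arr.shape}"
            )
        if arr.shape != tuple(image_shape):
            raise ShapeMismatchError(
                f"mask {path} shape {arr.shape} != image shape {tuple(image_shape)}"
            )
        selected = arr > 0
    else:
        selected = _polygon_mask(spec, tuple(image_shape))
    if not selected.any():
        raise EmptyROIError(f"{label} ROI is empty")
    return ROIMask(selected=selected, label=label)


def warn_if_overlapping(lesional: ROIMask, perilesional: ROIMask) -> int:
    """Log a warning when the two ROIs share pixels; return the overlap count.

    Overlap violates the sampling design (the perilesional ROI should be
    disjoint baseline skin) but manual masks sometimes touch, so this is a
    warning rather than an error.
    """
    if lesional.selected.shape != perilesional.selected.shape:
        raise ShapeMismatchError("ROI masks have different shapes")
    overlap = int((lesional.selected & perilesional.selected).sum())
    if overlap:
        logger.warning(
            "lesional and perilesional ROIs overlap on %d pixels", overlap
        )
    return overlap


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def to_grayscale_8bit(img: RGBImage, mode: str = "unweighted_mean") -> np.ndarray:
    """Convert to an 8-bit grayscale plane under the selected dialect."""
    if mode not in GRAYSCALE_MODES:
        raise ValueError(f"mode must be one of {GRAYSCALE_MODES}, got {mode!r}")
    if mode == "unweighted_mean":
        s = (
            img.red.astype(np.int64)
            + img.green.astype(np.int64)
            + img.blue.astype(np.int64)
        )
        # floor(s/3 + 1/2) in exact integer arithmetic
        out = (2 * s + 3) // 6
    else:
        wr, wg, wb = ITU601_WEIGHTS
        luma = wr * img.red + wg * img.green + wb * img.blue
        out = _round_half_up(luma)
    return out.astype(np.uint8)


def composite_plane(img: RGBImage) -> np.ndarray:
    """Per-pixel unweighted mean of R, G, B — the composite "RGB" plane.

    Bit-identical to ``to_grayscale_8bit(img, "unweighted_mean")``, so the
    composite histogram entropy always equals the unweighted grayscale
    entropy: collapsing channels into one intensity plane discards chromatic
    structure by construction.
    """
    return to_grayscale_8bit(img, "unweighted_mean")
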