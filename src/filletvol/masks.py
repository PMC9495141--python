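"""Cross-sectional areas from binary contour masks by pixel counting.

Replaces manual contour tracing in an image-analysis GUI: a segmentation
exported as a binary PNG/TIFF mask, together with a physical pixel-size
calibration (cm per pixel side), yields the slice area as
``foreground pixel count × pixel_size²``. Calibration is always an explicit
input — per file via a CSV sidecar or per call — because exported masks
carry no trustworthy physical metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "MaskImage",
    "InvalidMaskError",
    "area_from_mask",
    "rasterize_ellipse",
    "read_mask",
    "read_pixel_sizes",
]


class InvalidMaskError(ValueError):
    """Raised when a raster is not strictly binary."""


@dataclass(frozen=True)
class MaskImage:
    """A 2-D binary raster (row-major, origin top-left) with calibration.

    ``grid`` is boolean; ``pixel_size`` is the physical side length of one
    pixel in cm.
    """

    grid: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise InvalidMaskError("mask must be a 2-D raster")
        if grid.dtype != bool:
            values = np.unique(grid)
            nonzero = values[values != 0]
            if nonzero.size > 1:
                raise InvalidMaskError(
                    "mask raster is not binary: found values "
                    f"{values[:5].tolist()}"
                )
            grid = grid != 0
        object.__setattr__(self, "grid", grid)


def area_from_mask(mask: MaskImage) -> float:
    """Slice area in cm^2: foreground pixel count times pixel_size^2."""
    return float(np.count_nonzero(mask.grid)) * mask.pixel_size**2


def rasterize_ellipse(a: float, b: float, pixel_size: float) -> MaskImage:
    """Rasterize an axis-aligned ellipse with semi-axes a, b (cm).

    A pixel is foreground iff its *center* lies inside the ellipse
    (unbiased to first order in pixel_size). The grid has odd dimensions
    centred on the ellipse, so the mask is symmetric about both axes.
    """
    if a <= 0 or b <= 0 or pixel_size <= 0:
        raise ValueError("semi-axes and pixel_size must be positive")
    half_x = math.ceil(a / pixel_size) + 1
    half_y = math.ceil(b / pixel_size) + 1
    xs = np.arange(-half_x, half_x + 1) * pixel_size
    ys = np.arange(-half_y, half_y + 1) * pixel_size
    inside = (xs[None, :] / a) ** 2 + (ys[:, None] / b) ** 2 <= 1.0
    return MaskImage(grid=inside, pixel_size=pixel_size)


def read_mask(path, pixel_size: float) -> MaskImage:
    """Read a PNG/TIFF mask; any integer dtype, nonzero = foreground.

    Multi-channel images are reduced by "any channel nonzero". Rasters with
    more than one distinct nonzero value are rejected as non-binary.
    """
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = np.max(raw, axis=-1)
    return MaskImage(grid=raw, pixel_size=pixel_size)


def read_pixel_sizes(path) -> dict[str, float]:
    """Read a calibration sidecar CSV with columns filename, pixel_size_cm."""
    frame = pd.read_csv(path)
    missing = {"filename", "pixel_size_cm"} - set(frame.columns)
    if missing:
        raise ValueError(f"sidecar is missing columns: {sorted(missing)}")
    return dict(zip(frame["filename"], frame["pixel_size_cm"].astype(float)))
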