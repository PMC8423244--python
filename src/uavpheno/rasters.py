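"""Georeferenced raster I/O on GeoTIFF via tifffile.

The pipeline works in a local, metric, north-up Cartesian frame: x grows
east (right), y grows north (up), the raster origin is the *upper-left
corner* of pixel (0, 0). Georeferencing is stored in the standard GeoTIFF
tags (ModelPixelScaleTag 33550 and ModelTiepointTag 33922), which any GIS
reader understands; no geodetic CRS is attached because scenes live in a
local frame.

Pixel convention (used consistently across the package): pixel (row, col)
has its *center* at::

    x = origin_x + (col + 0.5) * xres
    y = origin_y - (row + 0.5) * yres
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import ConfigurationError, GeoreferencingError, InvalidParameterError

MODEL_PIXEL_SCALE_TAG = 33550
MODEL_TIEPOINT_TAG = 33922


@dataclass(frozen=True)
class GridTransform:
    """North-up affine map between pixel indices and world meters."""

    origin_x: float
    origin_y: float
    xres: float  # meters per pixel, > 0
    yres: float  # meters per pixel, > 0 (rows advance southwards)

    def __post_init__(self):
        if not (self.xres > 0 and self.yres > 0):
            raise InvalidParameterError("pixel resolutions must be positive")

    def pixel_center(self, rows, cols):
        """World coordinates of pixel centers."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        x = self.origin_x + (cols + 0.5) * self.xres
        y = self.origin_y - (rows + 0.5) * self.yres
        return x, y

    def world_to_pixel(self, x, y):
        """Fractional (row, col) of world points; (0, 0) maps to (-0.5, -0.5)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = (x - self.origin_x) / self.xres - 0.5
        row = (self.origin_y - y) / self.yres - 0.5
        return row, col

    @property
    def gsd_cm(self) -> float:
        """Ground sampling distance in cm/pixel (mean of axis resolutions)."""
        return 100.0 * 0.5 * (self.xres + self.yres)


@dataclass
class Raster:
    """In-memory raster: data as (bands, h, w) or (h, w) plus its transform."""

    data: np.ndarray
    transform: GridTransform
    band_names: tuple[str, ...] | None = None

    @property
    def n_bands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]


def write_raster(path, data, transform: GridTransform,
                 band_names: tuple[str, ...] | None = None) -> None:
    """Write a (h, w) or (bands, h, w) array as a georeferenced GeoTIFF."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (2, 3):
        raise ConfigurationError(f"raster must be 2-D or 3-D, got shape {data.shape}")
    extratags = [
        (MODEL_PIXEL_SCALE_TAG, "d", 3, (transform.xres, transform.yres, 0.0)),
        (MODEL_TIEPOINT_TAG, "d", 6,
         (0.0, 0.0, 0.0, transform.origin_x, transform.origin_y, 0.0)),
    ]
    metadata = {}
    if band_names is not None:
        if data.ndim != 3 or len(band_names) != data.shape[0]:
            raise ConfigurationError("band_names length must match band count")
        metadata["band_names"] = list(band_names)
    tifffile.imwrite(path, data, extratags=extratags, metadata=metadata,
                     photometric="minisblack")


def read_raster(path, expect_bands: int | None = None) -> Raster:
    """Read a GeoTIFF written by :func:`write_raster` (or any GeoTIFF with
    pixel-scale + tiepoint tags). Raises on missing georeferencing."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        tags = tif.pages[0].tags
        scale = tags.get(MODEL_PIXEL_SCALE_TAG)
        tiepoint = tags.get(MODEL_TIEPOINT_TAG)
        scale_value = None if scale is None else tuple(scale.value)
        tiepoint_value = None if tiepoint is None else tuple(tiepoint.value)
        band_names = None
        if tif.shaped_metadata:
            names = tif.shaped_metadata[0].get("band_names")
            if names:
                band_names = tuple(names)
    if scale_value is None or tiepoint_value is None:
        raise GeoreferencingError(
            f"{path}: missing GeoTIFF pixel-scale/tiepoint tags; "
            "cannot place raster in the world")
    sx, sy = float(scale_value[0]), float(scale_value[1])
    tp = tiepoint_value
    # tiepoint maps raster (i, j, k) -> world (x, y, z); we write (0,0,0).
    origin_x = float(tp[3]) - float(tp[0]) * sx
    origin_y = float(tp[4]) + float(tp[1]) * sy
    transform = GridTransform(origin_x, origin_y, sx, sy)
    n_bands = 1 if data.ndim == 2 else data.shape[0]
    if expect_bands is not None and n_bands != expect_bands:
        raise ConfigurationError(
            f"{path}: expected {expect_bands} band(s), found {n_bands}")
    return Raster(data=data, transform=transform, band_names=band_names)
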