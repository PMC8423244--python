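"""Plot and calibration-panel regions of interest.

ROIs are simple polygons in the scene's world frame (meters). They travel as
GeoJSON FeatureCollections; a feature's ``kind`` property distinguishes crop
plots from reflectance panels. Rasterization uses pixel-center sampling: a
pixel belongs to an ROI iff its center lies strictly inside the polygon.
This single convention backs panel extraction, canopy-area counting and
zonal VI means, so areas and means are mutually consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon, mapping, shape as _shape

from .errors import EmptyROIError, GeometryError, SchemaError
from .rasters import GridTransform

_PLOT_PROPS = ("plot_id", "entry", "replicate", "n_plants")
_PANEL_PROPS = ("panel_id", "reflectance")


@dataclass
class PlotROI:
    """One experimental plot: polygon + entry/replicate/stand-count metadata."""

    polygon: Polygon
    plot_id: str
    entry: str
    replicate: int
    n_plants: int


@dataclass
class PanelROI:
    """One radiometric calibration panel with its standard reflectance."""

    polygon: Polygon
    panel_id: str
    reflectance: float


def _validate_polygon(poly, label: str) -> Polygon:
    if not isinstance(poly, Polygon) or poly.is_empty:
        raise GeometryError(f"feature '{label}': geometry must be a non-empty Polygon")
    if not poly.is_valid:
        raise GeometryError(f"feature '{label}': polygon is invalid "
                            "(self-intersecting or degenerate)")
    return poly


def polygon_pixel_mask(polygon: Polygon, transform: GridTransform,
                       shape: tuple[int, int]) -> np.ndarray:
    """Boolean (h, w) mask of pixels whose centers fall inside ``polygon``.

    Only the polygon's bounding window is tested, so cost scales with the ROI,
    not with the raster.
    """
    h, w = shape
    minx, miny, maxx, maxy = polygon.bounds
    r0, c0 = transform.world_to_pixel(minx, maxy)
    r1, c1 = transform.world_to_pixel(maxx, miny)
    row_lo = max(int(np.floor(r0)), 0)
    col_lo = max(int(np.floor(c0)), 0)
    row_hi = min(int(np.ceil(r1)) + 1, h)
    col_hi = min(int(np.ceil(c1)) + 1, w)
    mask = np.zeros(shape, dtype=bool)
    if row_lo >= row_hi or col_lo >= col_hi:
        return mask
    rows = np.arange(row_lo, row_hi)
    cols = np.arange(col_lo, col_hi)
    cgrid, rgrid = np.meshgrid(cols, rows)
    x, y = transform.pixel_center(rgrid.ravel(), cgrid.ravel())
    inside = shapely.contains_xy(polygon, x, y)
    mask[row_lo:row_hi, col_lo:col_hi] = inside.reshape(rgrid.shape)
    return mask


def require_coverage(mask: np.ndarray, label: str) -> np.ndarray:
    if not mask.any():
        raise EmptyROIError(f"ROI '{label}' covers no pixel centers")
    return mask


def write_rois(path, plot_rois: list[PlotROI], panel_rois: list[PanelROI]) -> None:
    """Write plots and panels as one GeoJSON FeatureCollection."""
    features = []
    for p in plot_rois:
        features.append({
            "type": "Feature",
            "geometry": mapping(p.polygon),
            "properties": {"kind": "plot", "plot_id": p.plot_id, "entry": p.entry,
                           "replicate": int(p.replicate), "n_plants": int(p.n_plants)},
        })
    for p in panel_rois:
        features.append({
            "type": "Feature",
            "geometry": mapping(p.polygon),
            "properties": {"kind": "panel", "panel_id": p.panel_id,
                           "reflectance": float(p.reflectance)},
        })
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=1))


def read_rois(path) -> tuple[list[PlotROI], list[PanelROI]]:
    """Read a FeatureCollection of plot and panel ROIs, validating schema
    and geometry. Empty collections are an error: a scene without ROIs
    cannot be analyzed."""
    collection = json.loads(Path(path).read_text())
    features = collection.get("features", [])
    if not features:
        raise EmptyROIError(f"{path}: FeatureCollection has no features")
    plots: list[PlotROI] = []
    panels: list[PanelROI] = []
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        kind = props.get("kind")
        label = props.get("plot_id") or props.get("panel_id") or f"#{i}"
        geom = _validate_polygon(_shape(feat["geometry"]), label)
        if kind == "plot":
            missing = [k for k in _PLOT_PROPS if k not in props]
            if missing:
                raise SchemaError(f"plot feature '{label}' missing properties: {missing}")
            plots.append(PlotROI(geom, str(props["plot_id"]), str(props["entry"]),
                                 int(props["replicate"]), int(props["n_plants"])))
        elif kind == "panel":
            missing = [k for k in _PANEL_PROPS if k not in props]
            if missing:
                raise SchemaError(f"panel feature '{label}' missing properties: {missing}")
            panels.append(PanelROI(geom, str(props["panel_id"]),
                                   float(props["reflectance"])))
        else:
            raise SchemaError(f"feature '{label}': unknown or missing kind {kind!r}")
    return plots, panels
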