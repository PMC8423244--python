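"""Per-plot growth traits from calibrated imagery.

Three image-derived traits per plot and acquisition set:

* ``sur_cm2`` — canopy surface area per plant: canopy pixels inside the plot
  ROI times the squared ground sampling distance, divided by the plot's
  stand count (the number of plants that actually emerged, not the nominal
  seeding rate).
* ``eph_mm`` — estimated plant height: the maximum of DSM - DTM over the
  plot, in millimeters. Negative differences (reconstruction noise) are
  floored at zero before taking the maximum.
* six vegetation-index means over the plot ROI, either over all valid ROI
  pixels (default) or canopy pixels only.

Image traits are then joined with manually measured stem diameter (mm) and
node count on (plot_id, set) into one tidy table.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (ConfigurationError, DataIntegrityError, EmptyROIError,
                     InvalidParameterError)
from .rasters import GridTransform
from .rois import PlotROI, polygon_pixel_mask
from .vegindex import INDEX_NAMES, VIStack

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ["plot_id", "set", "entry", "rep", "sur_cm2", "eph_mm",
                 "sd_mm", "nn", *INDEX_NAMES, "n_canopy_px"]


def plot_surface_area(canopy_mask: np.ndarray, roi_mask: np.ndarray,
                      gsd_cm: float, n_plants: int) -> tuple[float, int]:
    """Per-plant canopy area in cm² and the canopy pixel count.

    A plot with ``n_plants == 0`` (non-germinated entry) yields NaN — an
    exclusion marker, not an error — so table builders can drop it cleanly.
    """
    if gsd_cm <= 0:
        raise InvalidParameterError(f"gsd must be positive, got {gsd_cm}")
    if n_plants < 0:
        raise InvalidParameterError(f"n_plants must be >= 0, got {n_plants}")
    n_px = int(np.count_nonzero(canopy_mask & roi_mask))
    if n_plants == 0:
        return math.nan, n_px
    return n_px * gsd_cm ** 2 / n_plants, n_px


def estimate_height(dsm: np.ndarray, dtm: np.ndarray, roi_mask: np.ndarray) -> float:
    """Max of (DSM - DTM) over the ROI, meters in, millimeters out."""
    if dsm.shape != dtm.shape:
        raise ConfigurationError(
            f"DSM shape {dsm.shape} and DTM shape {dtm.shape} differ")
    if not roi_mask.any():
        raise EmptyROIError("height ROI covers no pixel centers")
    chm = np.maximum(dsm.astype(float) - dtm.astype(float), 0.0)
    return float(chm[roi_mask].max() * 1000.0)


def plot_vi_means(vi_stack: VIStack, roi_mask: np.ndarray,
                  canopy_mask: np.ndarray | None = None,
                  mode: str = "all") -> dict[str, float]:
    """Arithmetic mean of each index over the selected valid pixels.

    ``mode='all'`` averages every valid ROI pixel; ``mode='canopy'``
    restricts to canopy pixels (requires ``canopy_mask``). A selection with
    zero pixels yields NaN for every index, logged, so the plot carries a
    missing-value marker instead of crashing the run.
    """
    if mode not in ("all", "canopy"):
        raise ConfigurationError(f"unknown VI-mean mode {mode!r}")
    sel = roi_mask.copy()
    if mode == "canopy":
        if canopy_mask is None:
            raise ConfigurationError("mode='canopy' requires a canopy mask")
        sel &= canopy_mask
    means: dict[str, float] = {}
    for name in INDEX_NAMES:
        values, valid = vi_stack.index(name)
        chosen = values[sel & valid]
        chosen = chosen[np.isfinite(chosen)]
        if chosen.size == 0:
            logger.warning("plot VI mean: no valid pixels selected for %s", name)
            means[name] = math.nan
        else:
            means[name] = float(chosen.mean())
    return means


def extract_image_traits(set_id: int, vi_stack: VIStack, canopy_mask: np.ndarray,
                         dsm: np.ndarray, dtm: np.ndarray, transform: GridTransform,
                         plot_rois: Iterable[PlotROI], gsd_cm: float,
                         vi_mode: str = "all") -> pd.DataFrame:
    """One row of image traits per germinated plot for one acquisition set.

    Plots with a zero stand count are dropped with a log entry.
    """
    rows = []
    for roi in plot_rois:
        if roi.n_plants == 0:
            logger.info("plot %s (entry %s): no emerged plants, excluded from traits",
                        roi.plot_id, roi.entry)
            continue
        roi_mask = polygon_pixel_mask(roi.polygon, transform, canopy_mask.shape)
        if not roi_mask.any():
            raise EmptyROIError(f"plot ROI '{roi.plot_id}' covers no pixel centers")
        sur, n_px = plot_surface_area(canopy_mask, roi_mask, gsd_cm, roi.n_plants)
        eph = estimate_height(dsm, dtm, roi_mask)
        vis = plot_vi_means(vi_stack, roi_mask, canopy_mask, mode=vi_mode)
        rows.append({"plot_id": roi.plot_id, "set": set_id, "entry": roi.entry,
                     "rep": roi.replicate, "sur_cm2": sur, "eph_mm": eph,
                     **vis, "n_canopy_px": n_px})
    return pd.DataFrame(rows)


def build_trait_table(image_traits: pd.DataFrame,
                      manual: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join image traits with the optional manual table on (plot_id, set).

    Manual columns are ``plot_id, set, sd_mm, nn``. Unmatched manual rows
    are reported via logging; duplicated (plot_id, set) keys in either input
    are a data-integrity error. Missing manual measurements stay NaN.
    """
    df = image_traits.copy()
    for key_df, label in ((df, "image traits"), (manual, "manual traits")):
        if key_df is not None and len(key_df) and \
                key_df.duplicated(subset=["plot_id", "set"]).any():
            dupes = key_df.loc[key_df.duplicated(subset=["plot_id", "set"]),
                               ["plot_id", "set"]]
            raise DataIntegrityError(
                f"duplicate (plot_id, set) keys in {label}: {dupes.values.tolist()}")
    if manual is not None and len(manual):
        manual = manual[["plot_id", "set", "sd_mm", "nn"]].copy()
        merged = df.merge(manual, on=["plot_id", "set"], how="left", indicator=True)
        unmatched = manual.merge(df[["plot_id", "set"]], on=["plot_id", "set"],
                                 how="left", indicator=True)
        n_orphans = int((unmatched["_merge"] == "left_only").sum())
        if n_orphans:
            logger.warning("build_trait_table: %d manual row(s) had no matching plot",
                           n_orphans)
        df = merged.drop(columns="_merge")
    else:
        df["sd_mm"] = math.nan
        df["nn"] = math.nan
    return df[TRAIT_COLUMNS].sort_values(["set", "plot_id"]).reset_index(drop=True)


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trait_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"plot_id": str, "entry": str})
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise DataIntegrityError(f"trait table {path} missing columns: {missing}")
    return df[TRAIT_COLUMNS]
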