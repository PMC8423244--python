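"""RGB chromatic coordinates, vegetation indices, and Otsu canopy masking.

Brightness-normalized chromatic coordinates r = R/(R+G+B), g = G/(R+G+B),
b = B/(R+G+B) remove illumination level and leave only color. Six standard
RGB vegetation indices are built from them:

    EXG  = 2g - r - b             excess green
    EXR  = 1.4r - g               excess red
    NDI  = (g - r) / (g + r)      normalized difference index
    EXGR = 3g - 2.4r - b          excess green minus excess red
    GLI  = (2g - b - r)/(2g + b + r)   green leaf index
    VARI = (g - r) / (g + r - b)  visible atmospherically resistant index

Under the r+g+b = 1 constraint, EXG = 3g - 1 and EXGR = EXG - EXR exactly;
EXG and GLI are both strictly increasing in g and hence rank pixels
identically. Canopy/background separation thresholds EXG with Otsu's
method: the threshold maximizing between-class variance over a fixed-bin
histogram of the observed EXG values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, DegenerateInputError, EmptyROIError
from .rasters import GridTransform
from .rois import PlotROI, polygon_pixel_mask

INDEX_NAMES = ("exg", "exgr", "exr", "ndi", "gli", "vari")


@dataclass
class ChromaticImage:
    """Per-pixel chromatic coordinates with a validity mask.

    Pixels where R+G+B = 0 carry no color information and are marked invalid
    (their coordinates are NaN); downstream statistics exclude them rather
    than propagate NaN or silently zero-fill.
    """

    r: np.ndarray
    g: np.ndarray
    b: np.ndarray
    valid: np.ndarray


@dataclass
class VIStack:
    """The six vegetation indices on a shared validity mask.

    ``vari_valid`` additionally excludes pixels where g + r - b = 0 (the
    VARI denominator); the other indices stay valid there. NDI pixels with
    g + r = 0 (pure blue) are NaN and excluded by the NaN-aware reductions
    used throughout.
    """

    exg: np.ndarray
    exgr: np.ndarray
    exr: np.ndarray
    ndi: np.ndarray
    gli: np.ndarray
    vari: np.ndarray
    valid: np.ndarray
    vari_valid: np.ndarray

    def index(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(values, validity mask) for one index name."""
        if name not in INDEX_NAMES:
            raise ConfigurationError(f"unknown index {name!r}; expected one of {INDEX_NAMES}")
        mask = self.vari_valid if name == "vari" else self.valid
        return getattr(self, name), mask


@dataclass
class OtsuResult:
    threshold: float
    between_class_variance: float
    histogram: np.ndarray
    bin_edges: np.ndarray


def chromatic_coords(reflectance: np.ndarray) -> ChromaticImage:
    """Normalize a (3, h, w) reflectance raster to chromatic coordinates."""
    reflectance = np.asarray(reflectance, dtype=float)
    if reflectance.ndim != 3 or reflectance.shape[0] != 3:
        raise ConfigurationError(
            f"expected a (3, h, w) raster, got shape {reflectance.shape}")
    total = reflectance.sum(axis=0)
    valid = total > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        coords = np.where(valid, reflectance / total, np.nan)
    return ChromaticImage(r=coords[0], g=coords[1], b=coords[2], valid=valid)


def compute_vis(chroma: ChromaticImage) -> VIStack:
    """All six indices from chromatic coordinates, on valid pixels only."""
    r, g, b = chroma.r, chroma.g, chroma.b
    with np.errstate(divide="ignore", invalid="ignore"):
        exg = 2.0 * g - r - b
        exr = 1.4 * r - g
        exgr = 3.0 * g - 2.4 * r - b
        ndi = np.where(g + r != 0, (g - r) / (g + r), np.nan)
        gli = np.where(2 * g + b + r != 0, (2 * g - b - r) / (2 * g + b + r), np.nan)
        vari_denom = g + r - b
        vari_ok = chroma.valid & (vari_denom != 0)
        vari = np.where(vari_ok, (g - r) / np.where(vari_ok, vari_denom, 1.0), np.nan)
    return VIStack(exg=exg, exgr=exgr, exr=exr, ndi=ndi, gli=gli, vari=vari,
                   valid=chroma.valid.copy(), vari_valid=vari_ok)


def otsu_threshold(values, bins: int = 256) -> OtsuResult:
    """Otsu's threshold of a 1-D value collection.

    A ``bins``-bin histogram spans the observed min-max range; the returned
    threshold is the bin edge maximizing the between-class variance, with
    both classes non-empty, so it lies strictly inside (min, max). Ties take
    the lowest edge. Deterministic for fixed input.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateInputError(
            "Otsu threshold needs >= 2 finite values with at least 2 distinct levels")
    counts, edges = np.histogram(values, bins=bins)
    p = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(p)[:-1]          # class weight below edge k+1
    m0 = np.cumsum(p * centers)[:-1]  # unnormalized class mean below
    mu_total = float(np.sum(p * centers))
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - m0) ** 2 / (w0 * w1)
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    k = int(np.argmax(sigma_b))
    return OtsuResult(threshold=float(edges[k + 1]),
                      between_class_variance=float(sigma_b[k]),
                      histogram=counts, bin_edges=edges)


def vegetation_mask(exg: np.ndarray, valid: np.ndarray, transform: GridTransform,
                    plot_rois: Iterable[PlotROI], threshold_scope: str = "global",
                    threshold: float | None = None, bins: int = 256,
                    ) -> tuple[np.ndarray, dict[str, float]]:
    """Canopy mask over the plot ROIs: pixel is canopy iff valid, inside an
    ROI, and EXG strictly exceeds the threshold.

    ``threshold_scope='global'`` computes one Otsu threshold over the union
    of ROI pixels (the default); ``'per-plot'`` thresholds each plot from its
    own histogram. An explicit ``threshold`` bypasses Otsu entirely.
    Returns the mask plus the threshold(s) actually used.
    """
    if threshold_scope not in ("global", "per-plot"):
        raise ConfigurationError(f"unknown threshold_scope {threshold_scope!r}")
    plot_rois = list(plot_rois)
    if not plot_rois:
        raise EmptyROIError("no plot ROIs supplied")
    shape = exg.shape
    roi_masks = {p.plot_id: polygon_pixel_mask(p.polygon, transform, shape)
                 for p in plot_rois}
    union = np.zeros(shape, dtype=bool)
    for m in roi_masks.values():
        union |= m
    if not union.any():
        raise EmptyROIError("plot ROI union covers no pixel centers")

    mask = np.zeros(shape, dtype=bool)
    thresholds: dict[str, float] = {}
    if threshold is not None:
        mask = union & valid & (exg > threshold)
        thresholds["explicit"] = float(threshold)
    elif threshold_scope == "global":
        t = otsu_threshold(exg[union & valid], bins=bins).threshold
        mask = union & valid & (exg > t)
        thresholds["global"] = t
    else:
        for plot_id, roi_mask in roi_masks.items():
            sel = roi_mask & valid
            if not sel.any():
                raise EmptyROIError(f"plot ROI '{plot_id}' covers no valid pixels")
            t = otsu_threshold(exg[sel], bins=bins).threshold
            thresholds[plot_id] = t
            mask |= sel & (exg > t)
    return mask, thresholds
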