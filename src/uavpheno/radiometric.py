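"""Exponential empirical-line radiometric calibration.

A UAV RGB sensor records digital numbers (DN), not surface reflectance, and
the mapping drifts with illumination between flights. The empirical line
method fixes this per flight using ground panels of known reflectance. Here
the per-band model is exponential,

    r_k = A_k * exp(B_k * DN),

so ln(r_k) is linear in DN and the fit is a closed-form ordinary least
squares on the log scale: deterministic, and exact when the panel samples
lie on the model. ``r2`` is therefore the coefficient of determination of
the *log-linear* regression — users comparing against goodness-of-fit
numbers computed on the raw scale should expect small differences.

Typical coefficient magnitudes for an 8-bit sensor are A ~ 0.004-0.01
(reflectance extrapolated to DN = 0) and B ~ 0.016-0.022 per DN.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .errors import (ConfigurationError, DomainError, EmptyROIError,
                     UnderdeterminedFitError)
from .rasters import GridTransform
from .rois import PanelROI, polygon_pixel_mask

logger = logging.getLogger(__name__)

BANDS = ("R", "G", "B")

#: Standard reflectances of the four-panel calibration target set.
STANDARD_PANEL_REFLECTANCES = (0.03, 0.12, 0.36, 0.56)


@dataclass(frozen=True)
class CalibrationSample:
    """One (panel, band) observation: mean DN paired with known reflectance."""

    band: str
    dn: float
    reflectance: float

    def __post_init__(self):
        if self.band not in BANDS:
            raise ConfigurationError(f"unknown band {self.band!r}; expected one of {BANDS}")
        if not (0.0 < self.reflectance <= 1.0):
            raise DomainError(
                f"reflectance must be in (0, 1] for a log fit, got {self.reflectance}")


@dataclass(frozen=True)
class BandCoefficients:
    a: float  # reflectance at DN = 0; > 0
    b: float  # per-DN rate
    r2: float
    n_samples: int

    def __post_init__(self):
        if self.a <= 0:
            raise DomainError(f"coefficient A must be positive, got {self.a}")


@dataclass(frozen=True)
class ELMModel:
    """Per-band (A, B, r2) of the exponential empirical-line model."""

    bands: Mapping[str, BandCoefficients]

    def __post_init__(self):
        if set(self.bands) != set(BANDS):
            raise ConfigurationError(
                f"ELM model must have exactly the bands {BANDS}, got {tuple(self.bands)}")

    def __getitem__(self, band: str) -> BandCoefficients:
        return self.bands[band]

    def reflectance(self, band: str, dn):
        c = self.bands[band]
        return c.a * np.exp(c.b * np.asarray(dn, dtype=float))

    def invert(self, band: str, reflectance):
        """DN at which the model yields ``reflectance``: ln(r/A)/B."""
        c = self.bands[band]
        r = np.asarray(reflectance, dtype=float)
        if np.any(r <= 0):
            raise DomainError(f"band {band}: reflectance must be positive to invert")
        return np.log(r / c.a) / c.b

    def to_dict(self) -> dict:
        return {band: {"A": c.a, "B": c.b, "r2": c.r2, "n": c.n_samples}
                for band, c in self.bands.items()}

    @classmethod
    def from_coefficients(cls, coeffs: Mapping[str, tuple[float, float]],
                          r2: float = 1.0, n: int = 0) -> "ELMModel":
        """Build a model from bare (A, B) pairs, e.g. published coefficients."""
        return cls({band: BandCoefficients(a, b, r2, n)
                    for band, (a, b) in coeffs.items()})

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def read_json(cls, path) -> "ELMModel":
        raw = json.loads(Path(path).read_text())
        return cls({band: BandCoefficients(v["A"], v["B"], v["r2"], v["n"])
                    for band, v in raw.items()})


def extract_panel_samples(dn_raster: np.ndarray, transform: GridTransform,
                          panel_rois: Iterable[PanelROI],
                          sensor_range: tuple[int, int] | None = None,
                          ) -> list[CalibrationSample]:
    """Mean DN over each panel ROI, per band, paired with the panel's
    standard reflectance.

    Pixels sitting at the extremes of the sensor range (saturated or zero)
    violate the exponential model and are excluded from the mean, with a
    warning. ``sensor_range`` defaults to the full range of an integer dtype
    and to no exclusion for float rasters.
    """
    dn_raster = np.asarray(dn_raster)
    if dn_raster.ndim != 3 or dn_raster.shape[0] != len(BANDS):
        raise ConfigurationError(
            f"DN raster must be (3, h, w), got shape {dn_raster.shape}")
    if sensor_range is None and np.issubdtype(dn_raster.dtype, np.integer):
        info = np.iinfo(dn_raster.dtype)
        sensor_range = (info.min, info.max)

    panel_rois = list(panel_rois)
    if not panel_rois:
        raise EmptyROIError("no panel ROIs supplied")
    samples: list[CalibrationSample] = []
    for panel in panel_rois:
        mask = polygon_pixel_mask(panel.polygon, transform, dn_raster.shape[1:])
        if not mask.any():
            raise EmptyROIError(f"panel ROI '{panel.panel_id}' covers no pixel centers")
        for bi, band in enumerate(BANDS):
            vals = dn_raster[bi][mask].astype(float)
            if sensor_range is not None:
                ok = (vals > sensor_range[0]) & (vals < sensor_range[1])
                n_flagged = vals.size - int(ok.sum())
                if n_flagged:
                    warnings.warn(
                        f"panel '{panel.panel_id}' band {band}: excluded {n_flagged} "
                        "pixel(s) at the sensor-range extremes from the panel mean")
                if ok.any():
                    vals = vals[ok]
                else:
                    raise EmptyROIError(
                        f"panel ROI '{panel.panel_id}' band {band}: all pixels saturated/zero")
            samples.append(CalibrationSample(band=band, dn=float(vals.mean()),
                                             reflectance=panel.reflectance))
    return samples


def fit_elm(samples: Iterable[CalibrationSample]) -> ELMModel:
    """Least-squares fit of ln(r) = ln(A) + B*DN per band.

    Exact (to numerical precision) when the samples lie on the model; raises
    when any band has fewer than two distinct DN values.
    """
    by_band: dict[str, list[CalibrationSample]] = {band: [] for band in BANDS}
    for s in samples:
        by_band[s.band].append(s)
    fits: dict[str, BandCoefficients] = {}
    for band in BANDS:
        group = by_band[band]
        dns = np.array([s.dn for s in group], dtype=float)
        if len(set(dns.tolist())) < 2:
            raise UnderdeterminedFitError(
                f"band {band}: need >= 2 samples with distinct DN, got {len(group)}")
        refl = np.array([s.reflectance for s in group], dtype=float)
        y = np.log(refl)
        slope, intercept = np.polyfit(dns, y, 1)
        yhat = intercept + slope * dns
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            r2 = 1.0 if ss_res < 1e-24 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        fits[band] = BandCoefficients(a=float(np.exp(intercept)), b=float(slope),
                                      r2=float(np.clip(r2, 0.0, 1.0)), n_samples=len(group))
    return ELMModel(fits)


def apply_elm(model: ELMModel, dn_raster: np.ndarray,
              band_order: tuple[str, ...] = BANDS) -> tuple[np.ndarray, int]:
    """Convert a (3, h, w) DN raster to reflectance, r = A*exp(B*DN).

    Output is float32, clipped to [0, 1]; returns the raster and the number
    of pixels that needed clipping.
    """
    dn_raster = np.asarray(dn_raster)
    if dn_raster.ndim != 3 or dn_raster.shape[0] != len(band_order):
        raise ConfigurationError(
            f"DN raster shape {dn_raster.shape} does not match bands {band_order}")
    if set(band_order) != set(BANDS):
        raise ConfigurationError(
            f"band order {band_order} does not match model bands {tuple(model.bands)}")
    out = np.empty(dn_raster.shape, dtype=np.float32)
    n_clipped = 0
    for bi, band in enumerate(band_order):
        r = model.reflectance(band, dn_raster[bi])
        n_clipped += int(np.count_nonzero((r < 0.0) | (r > 1.0)))
        out[bi] = np.clip(r, 0.0, 1.0)
    if n_clipped:
        logger.info("apply_elm: clipped %d pixel value(s) to [0, 1]", n_clipped)
    return out, n_clipped
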