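"""Synthetic UAV field scenes with known ground truth.

The generator emulates a plot-trial field the way the downstream pipeline
sees one: a georeferenced 3-band digital-number (DN) orthoimage, DSM and
DTM rasters on the same grid, four radiometric calibration panels, one ROI
polygon per plot, and a ground-truth trait table. The emulated design is a
kenaf-style trial: 24 entries x 3 replicates = 72 plots, up to 15 plants
per plot sown 25 cm apart on dark plastic mulch, panels at 3/12/36/56 %
reflectance, and two acquisition sets (1 = early, 2 = late growth stage).

Plants are rendered as quasi-circular canopy disks whose color is dominated
by green (a per-plot chromatic green fraction g); the mulch background is
dark and spectrally flat. The DSM is the DTM plus a dome-shaped canopy
height surface whose apex equals the plot's true plant height. DN values
are produced by *inverting* the exponential empirical-line model per band,
DN = ln(r/A_k)/B_k, then optionally adding Gaussian DN noise and quantizing
to the configured bit depth — so the calibration stage faces exactly the
forward problem it is built to solve.

Ground-truth traits for the two sets share a common latent growth factor
with configurable loadings: late-stage (set 2) traits load strongly and
positively on it, early-stage (set 1) traits only weakly, reproducing the
qualitative correlation structure of late-season canopy trials (all green
indices positively, the excess-red index negatively, associated with
growth). Identical (configuration, seed) pairs give bit-identical outputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import GenerationError, InvalidParameterError
from .radiometric import BANDS, ELMModel
from .rasters import GridTransform, write_raster
from .rois import PanelROI, PlotROI, write_rois

#: Standard panel reflectances of the emulated four-panel target set.
PANEL_REFLECTANCES = (0.03, 0.12, 0.36, 0.56)

#: Default per-set exponential-calibration truth (A, B) per band, taken from
#: published per-flight fits for an early- and a late-season flight of the
#: emulated campaign.
DEFAULT_ELM_TRUTH: Mapping[int, ELMModel] = {
    1: ELMModel.from_coefficients({"R": (0.0095, 0.0165),
                                   "G": (0.0066, 0.0178),
                                   "B": (0.0043, 0.0192)}),
    2: ELMModel.from_coefficients({"R": (0.0042, 0.0211),
                                   "G": (0.0043, 0.0210),
                                   "B": (0.0037, 0.0217)}),
}


# ----------------------------------------------------------------- camera

@dataclass(frozen=True)
class CameraModel:
    """Pinhole geometry of the nadir-pointing RGB camera."""

    horizontal_fov_deg: float = 72.3
    vertical_fov_deg: float = 57.5
    image_width_px: int = 4000
    image_height_px: int = 3000
    altitude_m: float = 40.0

    def __post_init__(self):
        for name in ("horizontal_fov_deg", "vertical_fov_deg",
                     "image_width_px", "image_height_px", "altitude_m"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"camera {name} must be positive")
        if self.horizontal_fov_deg >= 180 or self.vertical_fov_deg >= 180:
            raise InvalidParameterError("field of view must be below 180 degrees")


def nominal_gsd(camera: CameraModel) -> float:
    """Nominal ground sampling distance in cm/pixel at nadir.

    The swath covered on the ground is 2 * altitude * tan(hfov/2); dividing
    by the image width gives the per-pixel footprint.
    """
    half = math.radians(camera.horizontal_fov_deg / 2.0)
    return 100.0 * 2.0 * camera.altitude_m * math.tan(half) / camera.image_width_px


# ----------------------------------------------------------------- layout

@dataclass(frozen=True)
class FieldLayout:
    """Trial design: entries x replicates, stand geometry, germination."""

    n_entries: int = 24
    n_replicates: int = 3
    plants_per_plot: int = 15     # seeds sown per plot
    plant_spacing_cm: float = 25.0
    plot_size_cm: tuple[float, float] = (400.0, 100.0)
    germination_rate: float = 0.85
    dropout_entries: tuple[str, ...] = ("E02",)  # entries that never emerge

    def __post_init__(self):
        if self.n_entries < 1 or self.n_replicates < 1:
            raise InvalidParameterError("need at least 1 entry and 1 replicate")
        if self.plants_per_plot < 1:
            raise InvalidParameterError("plants_per_plot must be >= 1")
        if not (0.0 < self.germination_rate <= 1.0):
            raise InvalidParameterError("germination_rate must be in (0, 1]")

    @property
    def total_plots(self) -> int:
        return self.n_entries * self.n_replicates

    @property
    def entry_names(self) -> tuple[str, ...]:
        return tuple(f"E{i + 1:02d}" for i in range(self.n_entries))


def realize_layout(layout: FieldLayout, seed) -> pd.DataFrame:
    """Randomized complete assignment of entries to plot positions.

    Returns one row per plot: ``plot_id, grid_row, grid_col, entry, rep,
    n_plants, germinated`` where ``germinated`` is the per-seed-position
    emergence pattern (at least one plant emerges unless the entry is a
    dropout).
    """
    rng = np.random.default_rng(seed)
    slots = [entry for entry in layout.entry_names for _ in range(layout.n_replicates)]
    slots = [slots[i] for i in rng.permutation(len(slots))]
    rep_counter: dict[str, int] = {}
    rows = []
    n_cols = min(12, layout.total_plots)
    for idx, entry in enumerate(slots):
        rep_counter[entry] = rep_counter.get(entry, 0) + 1
        if entry in layout.dropout_entries:
            germinated = np.zeros(layout.plants_per_plot, dtype=bool)
        else:
            germinated = rng.random(layout.plants_per_plot) < layout.germination_rate
            if not germinated.any():
                germinated[layout.plants_per_plot // 2] = True
        rows.append({"plot_id": f"P{idx + 1:03d}",
                     "grid_row": idx // n_cols, "grid_col": idx % n_cols,
                     "entry": entry, "rep": rep_counter[entry],
                     "n_plants": int(germinated.sum()),
                     "germinated": tuple(bool(g) for g in germinated)})
    return pd.DataFrame(rows)


# ----------------------------------------------------------- ground truth

@dataclass(frozen=True)
class TraitParams:
    """Location/scale of one trait plus its latent-factor structure.

    The trait value for plot i is ``mean + scale * (loading * z_i +
    noise_sd * eps_i)`` with z the shared standard-normal growth factor and
    eps independent noise; with loading² + noise_sd² = 1 the marginal SD is
    ``scale`` and the Pearson correlation between two traits is the product
    of their loadings.
    """

    mean: float
    scale: float
    loading: float
    noise_sd: float

    def __post_init__(self):
        if self.noise_sd < 0:
            raise InvalidParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.scale < 0:
            raise InvalidParameterError("scale must be >= 0")


def _balanced(mean, scale, loading):
    return TraitParams(mean, scale, loading, math.sqrt(max(0.0, 1.0 - loading ** 2)))


@dataclass(frozen=True)
class GrowthParams:
    """Per-set trait parameters. Units: height mm, per-plant canopy area
    cm², stem diameter mm, node count, greenness as chromatic g fraction."""

    height: TraitParams
    area: TraitParams
    stem_diameter: TraitParams
    nodes: TraitParams
    greenness: TraitParams


#: Study conditions: early-stage traits are nearly independent (weak latent
#: loadings), late-stage traits share a strong common growth factor
#: (loading 0.85 -> pairwise population Spearman rho ≈ 0.71 between traits).
DEFAULT_GROWTH: Mapping[int, GrowthParams] = {
    1: GrowthParams(height=_balanced(900.0, 150.0, 0.15),
                    area=_balanced(450.0, 100.0, 0.15),
                    stem_diameter=_balanced(8.0, 1.5, 0.15),
                    nodes=_balanced(10.0, 2.0, 0.15),
                    greenness=_balanced(0.45, 0.020, 0.15)),
    2: GrowthParams(height=_balanced(2600.0, 450.0, 0.85),
                    area=_balanced(1300.0, 280.0, 0.85),
                    stem_diameter=_balanced(16.0, 3.0, 0.85),
                    nodes=_balanced(25.0, 5.0, 0.85),
                    greenness=_balanced(0.48, 0.030, 0.85)),
}

_TRAIT_FIELDS = (("height_mm", "height"), ("area_cm2", "area"),
                 ("sd_mm", "stem_diameter"), ("nn", "nodes"),
                 ("g_frac", "greenness"))


def latent_pair_pearson(p1: TraitParams, p2: TraitParams) -> float:
    """Population Pearson correlation implied by the latent-factor model."""
    def total_sd(p):
        return math.hypot(p.loading, p.noise_sd)
    return p1.loading * p2.loading / (total_sd(p1) * total_sd(p2))


def generate_truth_traits(plots: pd.DataFrame,
                          growth: Mapping[int, GrowthParams] = DEFAULT_GROWTH,
                          seed=0, entry_effect: float = 0.6) -> pd.DataFrame:
    """Ground-truth trait table: one row per (plot, set).

    Within a set all traits are driven by one standard-normal latent growth
    factor per plot. ``entry_effect`` is the share of that factor's variance
    carried at the genotype (entry) level, so replicates of a vigorous entry
    are all vigorous — the between-entry differences a trial is designed to
    detect. Node counts are rounded to integers, greenness clipped to a
    plausible chromatic range, heights/areas floored at small positive
    values.
    """
    if not (0.0 <= entry_effect <= 1.0):
        raise InvalidParameterError("entry_effect must be in [0, 1]")
    rng = np.random.default_rng(seed)
    frames = []
    n = len(plots)
    entries = sorted(plots["entry"].unique())
    for set_id in sorted(growth):
        params = growth[set_id]
        u = dict(zip(entries, rng.standard_normal(len(entries))))
        z = (math.sqrt(entry_effect) * plots["entry"].map(u).to_numpy()
             + math.sqrt(1.0 - entry_effect) * rng.standard_normal(n))
        row = {"plot_id": plots["plot_id"].to_numpy(),
               "set": set_id,
               "entry": plots["entry"].to_numpy(),
               "rep": plots["rep"].to_numpy()}
        for col, attr in _TRAIT_FIELDS:
            p: TraitParams = getattr(params, attr)
            eps = rng.standard_normal(n)
            row[col] = p.mean + p.scale * (p.loading * z + p.noise_sd * eps)
        frames.append(pd.DataFrame(row))
    truth = pd.concat(frames, ignore_index=True)
    truth["height_mm"] = truth["height_mm"].clip(lower=50.0)
    truth["area_cm2"] = truth["area_cm2"].clip(lower=50.0)
    truth["sd_mm"] = truth["sd_mm"].clip(lower=1.0)
    truth["nn"] = truth["nn"].round().clip(lower=0).astype(int)
    # A live canopy is always distinctly greener than the spectrally neutral
    # mulch (g = 1/3); the floor keeps the dimmest plot visibly green.
    truth["g_frac"] = truth["g_frac"].clip(lower=0.42, upper=0.60)
    return truth


# ------------------------------------------------------------ scene model

@dataclass(frozen=True)
class NoiseParams:
    """Sensor imperfections applied after the ideal DN is computed."""

    dn_noise_sd: float = 0.5        # Gaussian DN noise, in DN
    quantize: bool = True           # round to integer DN
    bit_depth: int = 8              # 8 or 16
    dsm_noise_sd_m: float = 0.0     # Gaussian elevation noise on the DSM

    def __post_init__(self):
        if self.dn_noise_sd < 0 or self.dsm_noise_sd_m < 0:
            raise InvalidParameterError("noise SDs must be >= 0")
        if self.bit_depth not in (8, 16):
            raise InvalidParameterError("bit_depth must be 8 or 16")

    @property
    def max_dn(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class SceneGeometry:
    """Field geometry not part of the trial design proper.

    The mulch background is dark and spectrally flat (4 % in every band);
    the terrain is a gentle linear gradient (default 0.30 m across the
    field) so height extraction is tested against a non-flat DTM. Canopy
    disks are hard-edged so the pixel-count area oracle is exact;
    ``radius_jitter`` and the per-plant height range add within-plot
    variation.
    """

    margin_m: float = 1.0
    plot_gap_m: float = 0.5
    panel_size_m: float = 1.2
    panel_gap_m: float = 0.8
    panel_inset_m: float = 0.15
    panel_strip_gap_m: float = 1.0
    mulch_reflectance: float = 0.04
    canopy_brightness: float = 0.30  # sum of band reflectances inside canopy
    dtm_base_m: float = 50.0
    dtm_relief_m: float = 0.30
    radius_jitter: float = 0.10
    plant_height_range: tuple[float, float] = (0.70, 0.95)


@dataclass
class SyntheticScene:
    """One acquisition set: rasters + ROIs + per-set ground truth."""

    set_id: int
    dn: np.ndarray                 # (3, h, w), quantized or float DN
    dsm: np.ndarray                # (h, w) meters
    dtm: np.ndarray                # (h, w) meters
    transform: GridTransform
    gsd_cm: float
    panel_rois: list[PanelROI]
    plot_rois: list[PlotROI]
    truth: pd.DataFrame
    canopy_mask: np.ndarray        # (h, w) rendered truth mask
    elm_truth: ELMModel
    seed: int


def _reflectance_from_greenness(g: float, brightness: float) -> np.ndarray:
    """Band reflectances (R, G, B) of a canopy pixel with chromatic green
    fraction g; red and blue split the remainder evenly."""
    chroma = np.array([(1.0 - g) / 2.0, g, (1.0 - g) / 2.0])
    return chroma * brightness


def generate_scene(plots: pd.DataFrame, truth_set: pd.DataFrame, set_id: int,
                   elm_truth: ELMModel, layout: FieldLayout,
                   geometry: SceneGeometry = SceneGeometry(),
                   noise: NoiseParams = NoiseParams(),
                   gsd_cm: float | None = None, seed=0) -> SyntheticScene:
    """Render one acquisition set of the field.

    ``truth_set`` must hold the rows of ``plots`` for this set; its
    ``area_cm2`` column is *replaced* by the per-plant area actually
    rendered (pixel count x gsd², divided by the stand count), which is the
    quantity the surface-area trait estimates.
    """
    rng = np.random.default_rng(seed)
    if gsd_cm is None:
        gsd_cm = nominal_gsd(CameraModel())
    gsd_m = gsd_cm / 100.0

    plot_w, plot_h = (layout.plot_size_cm[0] / 100.0, layout.plot_size_cm[1] / 100.0)
    pitch_x = plot_w + geometry.plot_gap_m
    pitch_y = plot_h + geometry.plot_gap_m
    n_plots = len(plots)
    n_cols = int(plots["grid_col"].max()) + 1
    n_rows = int(plots["grid_row"].max()) + 1
    width_m = 2 * geometry.margin_m + n_cols * pitch_x - geometry.plot_gap_m
    plots_y0 = geometry.margin_m + geometry.panel_size_m + geometry.panel_strip_gap_m
    height_m = plots_y0 + n_rows * pitch_y - geometry.plot_gap_m + geometry.margin_m
    w = int(math.ceil(width_m / gsd_m))
    h = int(math.ceil(height_m / gsd_m))
    transform = GridTransform(origin_x=0.0, origin_y=height_m, xres=gsd_m, yres=gsd_m)

    refl = np.full((3, h, w), geometry.mulch_reflectance, dtype=np.float64)
    canopy_height = np.zeros((h, w), dtype=np.float64)
    canopy_mask = np.zeros((h, w), dtype=bool)

    # --- calibration panels along the top strip
    panel_rois: list[PanelROI] = []
    for k, r_std in enumerate(PANEL_REFLECTANCES):
        x0 = geometry.margin_m + k * (geometry.panel_size_m + geometry.panel_gap_m)
        y_top = height_m - geometry.margin_m
        square = box(x0, y_top - geometry.panel_size_m, x0 + geometry.panel_size_m, y_top)
        c0 = int(round(x0 / gsd_m))
        c1 = int(round((x0 + geometry.panel_size_m) / gsd_m))
        r0 = int(round((height_m - y_top) / gsd_m))
        r1 = int(round((height_m - y_top + geometry.panel_size_m) / gsd_m))
        refl[:, r0:r1, c0:c1] = r_std
        inset = geometry.panel_inset_m
        panel_rois.append(PanelROI(polygon=square.buffer(-inset, join_style="mitre"),
                                   panel_id=f"panel_{int(r_std * 100)}",
                                   reflectance=r_std))

    # --- plots
    truth_set = truth_set.set_index("plot_id", drop=False)
    plot_rois: list[PlotROI] = []
    rendered_area_cm2: dict[str, float] = {}
    spacing_m = layout.plant_spacing_cm / 100.0
    for rec in plots.itertuples():
        x0 = geometry.margin_m + rec.grid_col * pitch_x
        y_top = height_m - (plots_y0 + rec.grid_row * pitch_y)
        rect = box(x0, y_top - plot_h, x0 + plot_w, y_top)
        plot_rois.append(PlotROI(polygon=rect, plot_id=rec.plot_id, entry=rec.entry,
                                 replicate=int(rec.rep), n_plants=int(rec.n_plants)))
        if rec.n_plants == 0:
            rendered_area_cm2[rec.plot_id] = 0.0
            continue
        t = truth_set.loc[rec.plot_id]
        plant_height_m = float(t["height_mm"]) / 1000.0
        g = float(t["g_frac"])
        base_radius_m = math.sqrt(float(t["area_cm2"]) / math.pi) / 100.0
        emerged = [i for i, ok in enumerate(rec.germinated) if ok]
        n_sown = len(rec.germinated)
        cx = x0 + plot_w / 2.0
        cy = y_top - plot_h / 2.0
        tallest = emerged[int(rng.integers(len(emerged)))]
        lo, hi = geometry.plant_height_range
        heights = {i: plant_height_m * float(rng.uniform(lo, hi)) for i in emerged}
        heights[tallest] = plant_height_m
        radii = {i: base_radius_m * float(rng.uniform(1 - geometry.radius_jitter,
                                                      1 + geometry.radius_jitter))
                 for i in emerged}

        max_r = max(radii.values())
        pad = max_r + 2 * gsd_m
        r0 = max(int((height_m - (y_top + pad)) / gsd_m), 0)
        r1 = min(int((height_m - (y_top - plot_h - pad)) / gsd_m) + 1, h)
        c0 = max(int((x0 - pad) / gsd_m), 0)
        c1 = min(int((x0 + plot_w + pad) / gsd_m) + 1, w)
        rows = np.arange(r0, r1)
        cols = np.arange(c0, c1)
        xg, yg = transform.pixel_center(*np.meshgrid(rows, cols, indexing="ij"))

        local_mask = np.zeros(xg.shape, dtype=bool)
        local_h = np.zeros(xg.shape, dtype=np.float64)
        for i in emerged:
            px = cx + (i - (n_sown - 1) / 2.0) * spacing_m
            py = cy
            # snap the stem to the nearest pixel center so the dome apex is
            # sampled exactly and the height oracle is exact
            prow = int(round((height_m - py) / gsd_m - 0.5))
            pcol = int(round(px / gsd_m - 0.5))
            px, py = transform.pixel_center(prow, pcol)
            d2 = (xg - px) ** 2 + (yg - py) ** 2
            r2 = radii[i] ** 2
            inside = d2 < r2
            local_mask |= inside
            dome = heights[i] * np.sqrt(np.clip(1.0 - d2 / r2, 0.0, None))
            local_h = np.maximum(local_h, np.where(inside, dome, 0.0))

        bands = _reflectance_from_greenness(g, geometry.canopy_brightness)
        for bi in range(3):
            window = refl[bi, r0:r1, c0:c1]
            window[local_mask] = bands[bi]
        canopy_height[r0:r1, c0:c1] = np.maximum(canopy_height[r0:r1, c0:c1], local_h)
        canopy_mask[r0:r1, c0:c1] |= local_mask
        n_px = int(local_mask.sum())
        rendered_area_cm2[rec.plot_id] = n_px * gsd_cm ** 2 / rec.n_plants

    # --- terrain and surface
    x_centers = (np.arange(w) + 0.5) * gsd_m
    dtm = (geometry.dtm_base_m
           + geometry.dtm_relief_m * (x_centers / width_m)).astype(np.float64)
    dtm = np.broadcast_to(dtm, (h, w)).copy()
    dsm = dtm + canopy_height
    if noise.dsm_noise_sd_m > 0:
        dsm = dsm + rng.normal(0.0, noise.dsm_noise_sd_m, size=dsm.shape)
    dsm = dsm.astype(np.float32)
    dtm = dtm.astype(np.float32)

    # --- DN synthesis by inverting the calibration model
    dn = np.empty((3, h, w), dtype=np.float64)
    for bi, band in enumerate(BANDS):
        coef = elm_truth[band]
        r = refl[bi]
        if np.any(r <= 0):
            raise GenerationError(f"band {band}: non-positive reflectance cannot "
                                  "be inverted through the exponential model")
        vals = np.log(r / coef.a) / coef.b
        if vals.min() < -1e-9:
            raise GenerationError(
                f"band {band}: reflectance below the model floor A={coef.a} "
                "is outside the invertible DN range")
        if vals.max() > noise.max_dn:
            warnings.warn(f"band {band}: {int((vals > noise.max_dn).sum())} pixel(s) "
                          f"clipped at the top of the {noise.bit_depth}-bit range")
            vals = np.minimum(vals, noise.max_dn)
        dn[bi] = np.maximum(vals, 0.0)
    if noise.dn_noise_sd > 0:
        dn += rng.normal(0.0, noise.dn_noise_sd, size=dn.shape)
    if noise.quantize:
        dtype = np.uint8 if noise.bit_depth == 8 else np.uint16
        dn = np.clip(np.rint(dn), 0, noise.max_dn).astype(dtype)
    else:
        dn = dn.astype(np.float32)

    truth_out = truth_set.reset_index(drop=True).copy()
    truth_out["area_cm2"] = truth_out["plot_id"].map(rendered_area_cm2)
    truth_out.loc[truth_out["area_cm2"] == 0.0, "height_mm"] = 0.0
    seed_int = int(seed) if isinstance(seed, (int, np.integer)) else -1
    return SyntheticScene(set_id=set_id, dn=dn, dsm=dsm, dtm=dtm,
                          transform=transform, gsd_cm=gsd_cm,
                          panel_rois=panel_rois, plot_rois=plot_rois,
                          truth=truth_out, canopy_mask=canopy_mask,
                          elm_truth=elm_truth, seed=seed_int)


# ------------------------------------------------------------------ study

@dataclass
class Study:
    """Both acquisition sets of one simulated trial."""

    layout: FieldLayout
    plots: pd.DataFrame
    scenes: dict[int, SyntheticScene]
    truth: pd.DataFrame
    seed: int

    @property
    def manual_traits(self) -> pd.DataFrame:
        """The 'manually measured' trait table: stem diameter and node count
        per germinated plot and set, as a field crew would record them."""
        germinated = set(self.plots.loc[self.plots["n_plants"] > 0, "plot_id"])
        rows = self.truth[self.truth["plot_id"].isin(germinated)]
        return rows[["plot_id", "set", "sd_mm", "nn"]].reset_index(drop=True)


def generate_study(layout: FieldLayout = FieldLayout(),
                   growth: Mapping[int, GrowthParams] = DEFAULT_GROWTH,
                   elm_truth: Mapping[int, ELMModel] = DEFAULT_ELM_TRUTH,
                   geometry: SceneGeometry = SceneGeometry(),
                   noise: NoiseParams = NoiseParams(),
                   gsd_cm: float | None = None, seed: int = 0) -> Study:
    """Simulate the full trial: layout, truth traits, and one scene per set."""
    ss = np.random.SeedSequence(seed)
    layout_seed, truth_seed, *scene_seeds = ss.spawn(2 + len(growth))
    plots = realize_layout(layout, layout_seed)
    truth = generate_truth_traits(plots, growth, truth_seed)
    scenes: dict[int, SyntheticScene] = {}
    updated = []
    for scene_seed, set_id in zip(scene_seeds, sorted(growth)):
        truth_set = truth[truth["set"] == set_id].copy()
        scene = generate_scene(plots, truth_set, set_id, elm_truth[set_id],
                               layout, geometry=geometry, noise=noise,
                               gsd_cm=gsd_cm, seed=scene_seed)
        scene.seed = seed
        scenes[set_id] = scene
        updated.append(scene.truth)
    return Study(layout=layout, plots=plots, scenes=scenes,
                 truth=pd.concat(updated, ignore_index=True), seed=seed)


TRUTH_COLUMNS = ["plot_id", "set", "entry", "rep", "height_mm", "area_cm2",
                 "sd_mm", "nn", "g_frac"]


def write_study(study: Study, outdir) -> dict[str, Path]:
    """Write the study to disk: GeoTIFF rasters per set, one ROI GeoJSON,
    the truth table and the manual-trait table as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    first = study.scenes[min(study.scenes)]
    paths["rois"] = outdir / "rois.geojson"
    write_rois(paths["rois"], first.plot_rois, first.panel_rois)
    paths["truth"] = outdir / "truth.csv"
    study.truth[TRUTH_COLUMNS].to_csv(paths["truth"], index=False)
    paths["manual"] = outdir / "manual_traits.csv"
    study.manual_traits.to_csv(paths["manual"], index=False)
    for set_id, scene in study.scenes.items():
        set_dir = outdir / f"set{set_id}"
        set_dir.mkdir(exist_ok=True)
        write_raster(set_dir / "dn.tif", scene.dn, scene.transform,
                     band_names=BANDS)
        write_raster(set_dir / "dsm.tif", scene.dsm, scene.transform)
        write_raster(set_dir / "dtm.tif", scene.dtm, scene.transform)
        paths[f"set{set_id}"] = set_dir
    return paths
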