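"""End-to-end orchestration: simulate -> calibrate -> indices -> traits -> stats.

Each stage reads only files written by earlier stages (no stage mutates its
inputs), writes its products into the run directory, and drops a JSON
metadata sidecar (stage name, seed, config hash, package version) next to
every table so a run can be audited after the fact. A failure anywhere is
re-raised as :class:`PipelineStageError` carrying the stage name.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import PhenoError, PipelineStageError
from .radiometric import BANDS, apply_elm, extract_panel_samples, fit_elm
from .rasters import read_raster, write_raster
from .rois import read_rois
from .stats import trait_stats_report
from .synthetic_field import generate_study, write_study
from .traits import (build_trait_table, extract_image_traits, read_trait_table,
                     write_trait_table)
from .vegindex import INDEX_NAMES, VIStack, chromatic_coords, compute_vis, vegetation_mask

logger = logging.getLogger(__name__)


def _sidecar(path: Path, stage: str, config: PipelineConfig) -> None:
    meta = {"stage": stage, "seed": config.seed, "config_hash": config.config_hash,
            "uavpheno_version": __version__}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def _stage(name):
    """Decorator wrapping stage errors with the stage name."""
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except (PhenoError, OSError) as exc:
                raise PipelineStageError(name, str(exc)) from exc
        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped
    return deco


@_stage("simulate")
def stage_simulate(config: PipelineConfig, outdir) -> dict:
    """Generate the synthetic study and write its rasters, ROIs and truth."""
    study = generate_study(layout=config.layout(), noise=config.noise(),
                           gsd_cm=config.gsd_cm, seed=config.seed)
    paths = write_study(study, outdir)
    _sidecar(paths["truth"], "simulate", config)
    return paths


@_stage("calibrate")
def stage_calibrate(set_dir, rois_path, config: PipelineConfig) -> Path:
    """Fit the empirical-line model on the panels and write reflectance."""
    set_dir = Path(set_dir)
    dn = read_raster(set_dir / "dn.tif", expect_bands=3)
    _, panels = read_rois(rois_path)
    samples = extract_panel_samples(dn.data, dn.transform, panels)
    model = fit_elm(samples)
    refl, n_clipped = apply_elm(model, dn.data)
    out = set_dir / "reflectance.tif"
    write_raster(out, refl, dn.transform, band_names=BANDS)
    model.write_json(set_dir / "elm.json")
    _sidecar(set_dir / "elm.json", "calibrate", config)
    logger.info("calibrate %s: %s (clipped %d px)", set_dir.name,
                {b: round(model[b].r2, 4) for b in BANDS}, n_clipped)
    return out


@_stage("indices")
def stage_indices(set_dir, rois_path, config: PipelineConfig) -> Path:
    """Compute the six-index stack and the Otsu canopy mask."""
    set_dir = Path(set_dir)
    refl = read_raster(set_dir / "reflectance.tif", expect_bands=3)
    plots, _ = read_rois(rois_path)
    chroma = chromatic_coords(refl.data)
    vis = compute_vis(chroma)
    stack = np.stack([getattr(vis, name) for name in INDEX_NAMES]).astype(np.float32)
    write_raster(set_dir / "vi.tif", stack, refl.transform, band_names=INDEX_NAMES)
    mask, thresholds = vegetation_mask(vis.exg, vis.valid, refl.transform, plots,
                                       threshold_scope=config.otsu_scope)
    write_raster(set_dir / "mask.tif", mask.astype(np.uint8), refl.transform)
    (set_dir / "otsu.json").write_text(json.dumps(thresholds, indent=1))
    _sidecar(set_dir / "otsu.json", "indices", config)
    return set_dir / "vi.tif"


@_stage("traits")
def stage_traits(sim_dir, config: PipelineConfig, set_ids=(1, 2)) -> Path:
    """Extract per-plot traits for every set and join the manual table."""
    sim_dir = Path(sim_dir)
    plots, _ = read_rois(sim_dir / "rois.geojson")
    frames = []
    for set_id in set_ids:
        set_dir = sim_dir / f"set{set_id}"
        vi = read_raster(set_dir / "vi.tif", expect_bands=len(INDEX_NAMES))
        mask = read_raster(set_dir / "mask.tif").data.astype(bool)
        dsm = read_raster(set_dir / "dsm.tif").data
        dtm = read_raster(set_dir / "dtm.tif").data
        arrays = dict(zip(INDEX_NAMES, vi.data))
        finite = np.isfinite(vi.data).all(axis=0)
        stack = VIStack(**arrays, valid=np.isfinite(arrays["exg"]),
                        vari_valid=np.isfinite(arrays["vari"]))
        frames.append(extract_image_traits(
            set_id, stack, mask, dsm, dtm, vi.transform, plots,
            gsd_cm=vi.transform.gsd_cm, vi_mode=config.vi_mean_mode))
    image_traits = pd.concat(frames, ignore_index=True)
    manual_path = sim_dir / "manual_traits.csv"
    manual = pd.read_csv(manual_path, dtype={"plot_id": str}) if manual_path.exists() else None
    table = build_trait_table(image_traits, manual)
    out = sim_dir / "traits.csv"
    write_trait_table(table, out)
    _sidecar(out, "traits", config)
    return out


@_stage("stats")
def stage_stats(traits_path, outdir, config: PipelineConfig) -> Path:
    """Run the nonparametric statistics layer and write the report CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = read_trait_table(traits_path)
    report = trait_stats_report(table, alpha=config.alpha)
    for name, df in report.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=name.startswith("spearman"))
        _sidecar(path, "stats", config)
    lines = ["uavpheno statistical summary", f"alpha = {config.alpha}", ""]
    kw = report["kw_tests"]
    for rec in kw.itertuples():
        lines.append(f"set {rec.set} {rec.trait:>8s} [{rec.source:>5s}] "
                     f"H={rec.H:8.3f} df={rec.df} p={rec.p:.4g} {rec.signif}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return outdir


def run_pipeline(config: PipelineConfig, outdir) -> dict[str, Path]:
    """Run every stage in order on a fresh simulation. Deterministic for a
    fixed (config, seed): rerunning yields byte-identical trait tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = stage_simulate(config, outdir)
    rois = paths["rois"]
    for set_id in sorted(k for k in (1, 2) if f"set{k}" in paths):
        set_dir = paths[f"set{set_id}"]
        stage_calibrate(set_dir, rois, config)
        stage_indices(set_dir, rois, config)
    traits_path = stage_traits(outdir, config)
    stats_dir = stage_stats(traits_path, outdir / "stats", config)
    return {"simulation": outdir, "traits": traits_path, "stats": stats_dir}
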