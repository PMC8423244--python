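import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from uavpheno.radiometric import apply_elm, extract_panel_samples, fit_elm
from uavpheno.synthetic_field import FieldLayout, NoiseParams, generate_study
from uavpheno.traits import build_trait_table, extract_image_traits
from uavpheno.vegindex import chromatic_coords, compute_vis, vegetation_mask

#: A small, fully germinated trial at coarse GSD for fast unit tests.
SMALL_LAYOUT = FieldLayout(n_entries=4, n_replicates=2, plants_per_plot=5,
                           germination_rate=1.0, dropout_entries=())


@pytest.fixture(scope="session")
def small_study():
    return generate_study(layout=SMALL_LAYOUT, gsd_cm=4.0, seed=11)


@pytest.fixture(scope="session")
def clean_small_study():
    """Small study with sensor noise and quantization switched off."""
    return generate_study(layout=SMALL_LAYOUT, gsd_cm=4.0, seed=11,
                          noise=NoiseParams(dn_noise_sd=0.0, quantize=False))


@pytest.fixture(scope="session")
def default_study():
    """The full default trial: 24 entries x 3 reps, 15 plants, two sets."""
    return generate_study(seed=5)


def analyze_study(study, vi_mode: str = "all") -> pd.DataFrame:
    """Run the analysis chain in memory: panel calibration, indices, Otsu
    mask, per-plot trait extraction, manual-table join."""
    frames = []
    for set_id, scene in sorted(study.scenes.items()):
        model = fit_elm(extract_panel_samples(scene.dn, scene.transform,
                                              scene.panel_rois))
        refl, _ = apply_elm(model, scene.dn)
        vis = compute_vis(chromatic_coords(refl))
        mask, _ = vegetation_mask(vis.exg, vis.valid, scene.transform,
                                  scene.plot_rois)
        frames.append(extract_image_traits(
            set_id, vis, mask, scene.dsm, scene.dtm, scene.transform,
            scene.plot_rois, gsd_cm=scene.gsd_cm, vi_mode=vi_mode))
    return build_trait_table(pd.concat(frames, ignore_index=True),
                             study.manual_traits)


@pytest.fixture(scope="session")
def default_traits(default_study):
    return analyze_study(default_study)
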