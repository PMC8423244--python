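"""Pipeline configuration: a single flat YAML file, strictly validated.

Unknown keys are rejected by name rather than ignored, so typos in a config
fail loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synthetic_field import FieldLayout, NoiseParams


@dataclass
class PipelineConfig:
    seed: int = 0
    n_entries: int = 24
    n_replicates: int = 3
    plants_per_plot: int = 15
    plant_spacing_cm: float = 25.0
    germination_rate: float = 0.85
    dropout_entries: tuple[str, ...] = ("E02",)
    bit_depth: int = 8
    dn_noise_sd: float = 0.5
    dsm_noise_sd_m: float = 0.0
    gsd_cm: float | None = None          # None -> nominal camera GSD
    panel_reflectances: tuple[float, ...] = (0.03, 0.12, 0.36, 0.56)
    otsu_scope: str = "global"           # or "per-plot"
    vi_mean_mode: str = "all"            # or "canopy"
    alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self):
        if self.otsu_scope not in ("global", "per-plot"):
            raise ConfigurationError(f"otsu_scope must be 'global' or 'per-plot', "
                                     f"got {self.otsu_scope!r}")
        if self.vi_mean_mode not in ("all", "canopy"):
            raise ConfigurationError(f"vi_mean_mode must be 'all' or 'canopy', "
                                     f"got {self.vi_mean_mode!r}")
        if not (0 < self.alpha < 1):
            raise ConfigurationError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigurationError(f"{path}: unknown config key(s): {unknown}")
        for key in ("dropout_entries", "panel_reflectances"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **kwargs)

    def layout(self) -> FieldLayout:
        return FieldLayout(n_entries=self.n_entries, n_replicates=self.n_replicates,
                           plants_per_plot=self.plants_per_plot,
                           plant_spacing_cm=self.plant_spacing_cm,
                           germination_rate=self.germination_rate,
                           dropout_entries=tuple(self.dropout_entries))

    def noise(self) -> NoiseParams:
        return NoiseParams(dn_noise_sd=self.dn_noise_sd, bit_depth=self.bit_depth,
                           dsm_noise_sd_m=self.dsm_noise_sd_m)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dropout_entries"] = list(d["dropout_entries"])
        d["panel_reflectances"] = list(d["panel_reflectances"])
        return d

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
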