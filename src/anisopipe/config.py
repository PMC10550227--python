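"""Validated pipeline configuration loaded from a single YAML file."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import ConfigError

__all__ = ["PipelineConfig", "load_config", "dump_config"]


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticsSection(_Section):
    g_factor: Optional[float] = None  # None: estimate from the calibration pair
    numerical_aperture: float = 1.3
    refractive_index: float = 1.518


class PreprocessSection(_Section):
    background: float | list = 0.0
    lower_fraction: float = 0.05
    upper_fraction: float = 0.05
    threshold_mode: str = "range"


class AssaySection(_Section):
    phase_bounds: tuple[float, float, float] = (300.0, 600.0, 1200.0)
    use_fitted_endpoints: bool = True
    min_pixels: int = 1000


class SensorSection(_Section):
    r_mono: float = 0.40
    r_dimer: float = 0.20
    k_half: float = 50.0
    hill: float = 1.0
    brightness_dimer: float = 2.0


class KineticsSection(_Section):
    nadph_frac0: float = 0.9
    k_ox: float = 0.011552453009332421  # ln2 / 60 s
    k_red: float = 0.0023104906018664843  # ln2 / 300 s
    equilibrium_frac: float = 0.9
    pool_scale: float = 1.0


class ImagingSection(_Section):
    photons_per_pixel: float = 20000.0
    background_counts: float = 50.0
    g_factor_true: float = 1.25
    numerical_aperture: float = 1.3
    refractive_index: float = 1.518
    scatter_alpha_per_um: float = 0.004
    poisson_noise: bool = True
    seed: int = 0


class PhantomSection(_Section):
    shape: tuple[int, int] = (80, 80)
    n_cells: int = 30
    expression_median: float = 1.0
    expression_sigma_log: float = 0.3


class SimulateSection(_Section):
    sensor: SensorSection = SensorSection()
    kinetics: KineticsSection = KineticsSection()
    imaging: ImagingSection = ImagingSection()
    phantom: PhantomSection = PhantomSection()
    depth_um: float = 12.0
    dt_s: float = 10.0


class IoSection(_Section):
    output_dir: str = "anisopipe_out"
    stack: Optional[str] = None
    layout: Optional[dict] = None
    calibration_with: Optional[str] = None
    calibration_without: Optional[str] = None


class PipelineConfig(_Section):
    optics: OpticsSection = OpticsSection()
    preprocess: PreprocessSection = PreprocessSection()
    assay: AssaySection = AssaySection()
    simulate: Optional[SimulateSection] = None
    io: IoSection = IoSection()


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as err:
        raise ConfigError(str(err)) from err


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (provenance for exact reruns)."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True))
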