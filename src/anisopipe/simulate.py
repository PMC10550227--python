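"""Forward simulator of an NADP+-driven homo-FRET anisotropy sensor.

The sensor is a monomer/homodimer switch: free NADP+ drives dimerization,
dimers homo-FRET and depolarize their emission, so the ensemble anisotropy
falls from the monomer bound (r_mono, the monomer-locked control) toward the
dimer bound (r_dimer, the tandem-dimer control).  The chain simulated here:

    NADPH fraction kinetics  ->  dimer fraction (Hill response to NADP+)
      ->  ensemble anisotropy (intensity-weighted mixture)
      ->  depth-dependent scatter depolarization
      ->  polarized image formation (high-NA mixing, channel gain,
          background offset, Poisson photon noise)

The oxidation-recovery protocol is the transient-oxidant assay: stable
baseline for 5 min, first-order NADPH oxidation while the oxidant is
perfused (5-10 min), first-order metabolic recovery after washout
(10-20 min), sampled every 10 s.  Every stochastic output is reproducible
from the seed carried in ImagingParams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .core import OpticsConfig, na_mixing_matrix
from .errors import ConfigError
from .io import CalibrationPair, PolarizedFrame, PolarizedStack
from .quantify import DEFAULT_PHASE_BOUNDS, AssayMetrics, AssayTrace

__all__ = [
    "SensorParams",
    "KineticsParams",
    "ImagingParams",
    "Phantom",
    "dimer_fraction",
    "ensemble_anisotropy",
    "simulate_kinetics",
    "apply_depth_scatter",
    "make_phantom",
    "render_stack",
    "render_calibration_pair",
    "simulate_assay",
]

# Theoretical ceiling of the initial anisotropy under two-photon excitation
# (photoselection ~cos^4, r0 = 4/7).
TWO_PHOTON_R_MAX = 4.0 / 7.0


@dataclass(frozen=True)
class SensorParams:
    """Photophysical parameters of the monomer/dimer sensor ensemble.

    r_mono / r_dimer are the monomer-locked and tandem-dimer control
    anisotropies bounding the dynamic range; k_half is the NADP+ level (as a
    fraction of the reference pool) at half-maximal dimerization and hill its
    cooperativity.  Defaults are plausible in-vivo values, not measured ones.
    The default k_half places free NADP+ far below sensor saturation, so the
    anisotropy readout is proportional to the NADPH fraction -- the
    pseudo-linear operating regime in which trace half-lives report the
    underlying pool kinetics (the assay's working assumption).
    """

    r_mono: float = 0.40
    r_dimer: float = 0.20
    k_half: float = 50.0
    hill: float = 1.0
    brightness_dimer: float = 2.0

    def __post_init__(self) -> None:
        if not self.r_dimer < self.r_mono:
            raise ConfigError("r_dimer must lie below r_mono")
        if self.r_mono > TWO_PHOTON_R_MAX:
            raise ConfigError(
                f"r_mono exceeds the two-photon ceiling {TWO_PHOTON_R_MAX:.4f}"
            )
        if self.k_half <= 0:
            raise ConfigError("k_half must be positive")
        if self.hill < 1:
            raise ConfigError("hill exponent must be >= 1")
        if self.brightness_dimer <= 0:
            raise ConfigError("brightness_dimer must be positive")


@dataclass(frozen=True)
class KineticsParams:
    """First-order oxidation/recovery kinetics of the NADPH pool.

    k_ox acts while the oxidant is present (defaults give a 60-s depletion
    half-life), k_red during washout recovery (300-s half-life).  pool_scale
    models kinase-driven expansion of the total NADP(H) pool as a scalar on
    the absolute NADP+ concentration seen by the sensor; the expansion ramps
    in linearly over the recovery phase (continuous at the washout boundary),
    so at the assay end the sensor sees pool_scale times the reference pool.
    A constant scale would cancel between the baseline and the 20-min point
    and could not move the measured baseline.
    """

    nadph_frac0: float = 0.9
    k_ox: float = math.log(2.0) / 60.0
    k_red: float = math.log(2.0) / 300.0
    equilibrium_frac: float = 0.9
    pool_scale: float = 1.0
    phase_bounds: tuple[float, float, float] = DEFAULT_PHASE_BOUNDS

    def __post_init__(self) -> None:
        for name, v in (("nadph_frac0", self.nadph_frac0), ("equilibrium_frac", self.equilibrium_frac)):
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.k_ox < 0 or self.k_red < 0:
            raise ConfigError("rates must be non-negative")
        if self.pool_scale < 1.0:
            raise ConfigError("pool_scale models pool expansion and must be >= 1")


@dataclass(frozen=True)
class ImagingParams:
    """Image-formation parameters: photon budget, optics and noise.

    scatter_alpha_per_um is the fraction of photons replaced by fully
    depolarized scattered light per micrometre of imaging depth.
    """

    photons_per_pixel: float = 20000.0
    background_counts: float = 50.0
    g_factor_true: float = 1.25
    numerical_aperture: float = 1.3
    refractive_index: float = 1.518
    scatter_alpha_per_um: float = 0.004
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_per_pixel <= 0:
            raise ConfigError("photons_per_pixel must be positive")
        if self.background_counts < 0:
            raise ConfigError("background_counts must be non-negative")
        if self.g_factor_true <= 0:
            raise ConfigError("g_factor_true must be positive")
        if self.scatter_alpha_per_um < 0:
            raise ConfigError("scatter_alpha_per_um must be non-negative")

    def optics(self, g_factor: float | None = None) -> OpticsConfig:
        """Matching OpticsConfig (true G by default) for forward mixing."""
        return OpticsConfig(
            g_factor=self.g_factor_true if g_factor is None else g_factor,
            numerical_aperture=self.numerical_aperture,
            refractive_index=self.refractive_index,
        )


@dataclass(frozen=True)
class Phantom:
    """Islet-shaped expression raster with per-cell variability."""

    expression: np.ndarray
    cell_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        expr = np.asarray(self.expression, dtype=float)
        if (expr < 0).any():
            raise ConfigError("expression must be non-negative")
        object.__setattr__(self, "expression", expr)

    @property
    def support(self) -> np.ndarray:
        return self.expression > 0


def dimer_fraction(nadp_frac, params: SensorParams):
    """Hill-form dimerized fraction of the sensor at a given NADP+ level.

    f_d = x^h / (k_half^h + x^h) with x the NADP+ concentration expressed as
    a fraction of the reference pool (x >= 0; pool expansion can push it
    above 1).  Monotone increasing, f_d in [0, 1).
    """
    x = np.asarray(nadp_frac, dtype=float)
    if (x < 0).any():
        raise ConfigError("nadp_frac must be non-negative")
    h = params.hill
    num = x**h
    out = num / (params.k_half**h + num)
    return float(out) if out.ndim == 0 else out


def ensemble_anisotropy(f_d, params: SensorParams):
    """Intensity-weighted steady-state anisotropy of a monomer/dimer mixture.

    Additivity of anisotropies holds with photon-contribution weights; each
    dimer is brightness_dimer times as bright as a monomer, so

        w_dimer = f_d * b / (f_d * b + (1 - f_d)),   b = brightness_dimer
        r = w_dimer * r_dimer + (1 - w_dimer) * r_mono
    """
    f = np.asarray(f_d, dtype=float)
    if (f < 0).any() or (f > 1).any():
        raise ConfigError("f_d must lie in [0, 1]")
    b = params.brightness_dimer
    w = f * b / (f * b + (1.0 - f))
    r = w * params.r_dimer + (1.0 - w) * params.r_mono
    return float(r) if r.ndim == 0 else r


def simulate_kinetics(params: KineticsParams, times) -> np.ndarray:
    """Ground-truth NADPH fraction over the assay, as a piecewise closed form.

    Constant at nadph_frac0 over the baseline; exponential decay toward zero
    at rate k_ox during the oxidant phase; exponential relaxation toward
    equilibrium_frac at rate k_red during recovery.  Continuous at the
    phase boundaries.
    """
    t = np.asarray(times, dtype=float)
    b1, b2, b3 = params.phase_bounds
    if (t < 0).any() or (t > b3 + 1e-9).any():
        raise ConfigError("times must lie within the assay span")
    f0, feq = params.nadph_frac0, params.equilibrium_frac
    f_at_b2 = f0 * math.exp(-params.k_ox * (b2 - b1))
    out = np.where(
        t < b1,
        f0,
        np.where(
            t < b2,
            f0 * np.exp(-params.k_ox * np.clip(t - b1, 0, None)),
            feq + (f_at_b2 - feq) * np.exp(-params.k_red * np.clip(t - b2, 0, None)),
        ),
    )
    return out


def apply_depth_scatter(r_true, depth_um: float, params: ImagingParams):
    """Observed anisotropy after depth-proportional scatter depolarization.

    A fraction alpha = scatter_alpha_per_um * depth of the collected photons
    is replaced by fully depolarized scattered light, so r_obs = (1 - alpha) * r_true.
    The dynamic range between any two sensor states shrinks by the same factor.
    """
    if depth_um < 0:
        raise ConfigError("depth must be non-negative")
    alpha = params.scatter_alpha_per_um * depth_um
    if alpha >= 1.0:
        raise ConfigError("scatter fraction reaches 1 at this depth; model invalid")
    r = (1.0 - alpha) * np.asarray(r_true, dtype=float)
    return float(r) if r.ndim == 0 else r


def make_phantom(
    shape: tuple[int, int],
    n_cells: int,
    seed: int,
    expression_median: float = 1.0,
    expression_sigma_log: float = 0.3,
) -> Phantom:
    """Elliptical islet-shaped phantom tiled into Voronoi-like cells.

    Per-cell expression is lognormal (median ``expression_median``, log-SD
    ``expression_sigma_log``), mimicking cell-to-cell variation in sensor
    concentration; expression is zero outside the islet support.
    """
    h, w = shape
    if h < 4 or w < 4:
        raise ConfigError("phantom shape too small")
    if n_cells < 1:
        raise ConfigError("need at least one cell")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ay, ax = 0.45 * h, 0.45 * w
    support = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
    pts = np.column_stack(np.nonzero(support))
    seeds = pts[rng.choice(pts.shape[0], size=n_cells, replace=False)]
    labels = np.zeros(shape, dtype=int)
    if n_cells == 1:
        labels[support] = 1
        levels = np.array([expression_median])
    else:
        _, nearest = cKDTree(seeds).query(pts)
        labels[pts[:, 0], pts[:, 1]] = nearest + 1
        levels = expression_median * rng.lognormal(
            mean=0.0, sigma=expression_sigma_log, size=n_cells
        )
    expression = np.zeros(shape)
    inside = labels > 0
    expression[inside] = levels[labels[inside] - 1]
    return Phantom(expression=expression, cell_labels=labels)


def _render_frame(
    expression: np.ndarray,
    r_frame: np.ndarray,
    imaging: ImagingParams,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected polarized channel pair for one frame, optionally Poisson-sampled."""
    s = imaging.photons_per_pixel * expression
    par_true = s * (1.0 + 2.0 * r_frame) / 3.0
    perp_true = s * (1.0 - r_frame) / 3.0
    if (par_true < 0).any() or (perp_true < 0).any():  # r outside [-0.5, 1]
        raise ConfigError("anisotropy field outside the physical range [-0.5, 1]")
    m = na_mixing_matrix(imaging.optics())
    par_obs = m[0, 0] * par_true + m[0, 1] * perp_true
    perp_obs = (m[1, 0] * par_true + m[1, 1] * perp_true) / imaging.g_factor_true
    par_obs = par_obs + imaging.background_counts
    perp_obs = perp_obs + imaging.background_counts
    if rng is not None:
        par_obs = rng.poisson(par_obs).astype(np.float64)
        perp_obs = rng.poisson(perp_obs).astype(np.float64)
    return par_obs, perp_obs


def render_stack(
    phantom: Phantom,
    r_field: np.ndarray,
    imaging: ImagingParams,
    axis_kind: str = "z",
    spacing: float | None = None,
    coords: Sequence[float] | None = None,
    pixel_size_um: float = 0.6,
) -> PolarizedStack:
    """Render a polarized stack from an anisotropy field over the phantom.

    ``r_field`` is either one 2-D frame, a per-frame 3-D array, or a 1-D
    array of per-frame uniform anisotropies.  The measurement model per
    pixel: total signal S = photons_per_pixel * expression, ideal channels
    I_par = S (1 + 2r)/3 and I_perp = S (1 - r)/3, forward high-NA mixing,
    perpendicular gain 1/G, additive background, then Poisson sampling when
    noise is enabled.
    """
    expr = phantom.expression
    r_field = np.asarray(r_field, dtype=float)
    if r_field.ndim == 0:
        frames_r = r_field[None, None, None] * np.ones((1,) + expr.shape)
    elif r_field.ndim == 1:
        frames_r = r_field[:, None, None] * np.ones((1,) + expr.shape)
    elif r_field.ndim == 2:
        frames_r = r_field[None]
    else:
        frames_r = r_field
    if frames_r.shape[1:] != expr.shape:
        raise ConfigError("r_field shape inconsistent with phantom")
    if spacing is None:
        spacing = 1.0 if axis_kind == "z" else 10.0
    rng = np.random.default_rng(imaging.seed) if imaging.poisson_noise else None
    pars, perps = [], []
    for r_frame in frames_r:
        p, q = _render_frame(expr, r_frame, imaging, rng)
        pars.append(p)
        perps.append(q)
    return PolarizedStack.from_arrays(
        np.stack(pars),
        np.stack(perps),
        axis_kind=axis_kind,
        spacing=spacing,
        pixel_size_um=pixel_size_um,
        coords=coords,
    )


def render_calibration_pair(
    imaging: ImagingParams, shape: tuple[int, int] = (64, 64)
) -> CalibrationPair:
    """Simulate the isotropic-dye calibration pair with and without a half-wave plate.

    The dye is isotropic (r = 0) and spatially uniform; the ideal plate swaps
    the true polarized components before the detection path applies its gain
    imbalance, so both images carry the same detector bias.  Background is
    omitted: calibration frames are assumed background-corrected upstream.
    """
    s = imaging.photons_per_pixel * np.ones(shape)
    third = s / 3.0
    rng = np.random.default_rng(imaging.seed) if imaging.poisson_noise else None

    def detect(par_true, perp_true):
        par = par_true.copy()
        perp = perp_true / imaging.g_factor_true
        if rng is not None:
            par = rng.poisson(par).astype(np.float64)
            perp = rng.poisson(perp).astype(np.float64)
        return par, perp

    wo_par, wo_perp = detect(third, third)
    w_par, w_perp = detect(third, third)  # plate swap is a no-op on r = 0 light
    without = PolarizedFrame(wo_par, wo_perp)
    withp = PolarizedFrame(w_par, w_perp)
    return CalibrationPair(with_hwp=withp, without_hwp=without)


def _true_metrics(
    r_of_t: np.ndarray, times: np.ndarray, kinetics: KineticsParams
) -> AssayMetrics:
    b1, b2, b3 = kinetics.phase_bounds
    r_at = lambda tt: float(np.interp(tt, times, r_of_t))
    dep_amp = abs(r_at(b2) - r_at(b1))
    rec_amp = abs(r_at(b3) - r_at(b2))
    return AssayMetrics(
        diamide_drop=r_at(b2) - r_at(b1),
        depletion_half_life_s=(math.log(2.0) / kinetics.k_ox)
        if kinetics.k_ox > 0 and dep_amp > 0
        else None,
        recovery_half_life_s=(math.log(2.0) / kinetics.k_red)
        if kinetics.k_red > 0 and rec_amp > 0
        else None,
        baseline_change=r_at(b3) - r_at(b1),
    )


def simulate_assay(
    sensor: SensorParams,
    kinetics: KineticsParams,
    imaging: ImagingParams,
    phantom: Phantom,
    depth_um: float = 12.0,
    dt_s: float = 10.0,
    locked_dimer_fraction: float | None = None,
) -> tuple[PolarizedStack, AssayTrace, AssayMetrics]:
    """Simulate the full transient-oxidation assay time series.

    Chains kinetics -> dimer fraction -> ensemble anisotropy -> depth
    scatter -> image formation at ``dt_s`` intervals over the assay span,
    imaged at a fixed depth (default 12 um, within the first quarter of the
    islet).  ``locked_dimer_fraction`` pins the sensor in one state
    (0 = monomer-locked control, 1 = tandem-dimer control), which must show
    no oxidant response.  Returns the rendered stack plus the analytic
    ground-truth trace and metrics.
    """
    b1, b2, b3 = kinetics.phase_bounds
    times = np.arange(0.0, b3 + dt_s / 2, dt_s)
    nadph = simulate_kinetics(kinetics, times)
    if locked_dimer_fraction is None:
        # kinase-driven pool expansion ramps in over the recovery phase
        ramp = np.clip((times - b2) / (b3 - b2), 0.0, 1.0)
        scale = 1.0 + (kinetics.pool_scale - 1.0) * ramp
        nadp_abs = scale * (1.0 - nadph)
        f_d = dimer_fraction(nadp_abs, sensor)
    else:
        f_d = np.full_like(times, float(locked_dimer_fraction))
    r_true = ensemble_anisotropy(f_d, sensor)
    r_obs = apply_depth_scatter(r_true, depth_um, imaging)
    stack = render_stack(
        phantom, r_obs, imaging, axis_kind="time", spacing=dt_s, coords=times
    )
    n_support = int(phantom.support.sum())
    truth_trace = AssayTrace(
        time_s=times,
        r_mean=r_obs,
        n_valid=np.full(times.shape, n_support, dtype=int),
        phase_bounds=kinetics.phase_bounds,
    )
    if locked_dimer_fraction is not None:
        truth = AssayMetrics(0.0, None, None, 0.0)
    else:
        truth = _true_metrics(r_obs, times, kinetics)
    return stack, truth_trace, truth
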