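"""Per-pixel steady-state fluorescence anisotropy.

The measured anisotropy of a fluorophore population is

    r = (I_par - G * I_perp) / (I_par + 2 * G * I_perp)

where G is the instrument factor balancing the detection efficiency of the
two polarized channels, measured with an isotropic dye imaged with and
without a half-wave plate.  Before the formula is applied, each frame is
background-subtracted and corrected for the polarization mixing introduced
by a high-NA objective (the classical aperture-integral Ka/Kb/Kc factors).
Pixels are masked by a threshold on the fraction of the total-intensity
range, so dim background and saturated pixels never enter the average.

Processing order: background subtraction -> high-NA correction -> range
threshold -> anisotropy formula.  All corrections are linear, so r is
invariant to overall intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .errors import ConfigError, DegenerateDataError
from .io import CalibrationPair, PolarizedFrame

__all__ = [
    "OpticsConfig",
    "PreprocessConfig",
    "AnisotropyMap",
    "compute_na_factors",
    "na_mixing_matrix",
    "subtract_background",
    "threshold_range",
    "estimate_g_factor",
    "apply_na_correction",
    "compute_anisotropy",
    "normalize_anisotropy",
    "median_filter_for_display",
]


def compute_na_factors(
    numerical_aperture: float, refractive_index: float
) -> tuple[float, float, float]:
    """Aperture-integral correction factors (Ka, Kb, Kc) for a high-NA objective.

    A dipole's far field collected over the objective's cone of half-angle
    theta = arcsin(NA / n) mixes the polarized components.  Integrating the
    projected field intensity over the cone gives, with c = cos(theta):

        Ka = (2 - 3c + c^3) / 3        axial-dipole leakage into both channels
        Kb = (5 - 3c - c^2 - c^3) / 4  co-polarized transmission
        Kc = (1 - c)^3 / 12            cross-polarized leakage

    As NA -> 0, Ka/Kb and Kc/Kb vanish and the collection becomes the ideal
    paraxial measurement.  Evaluation uses the equivalent polynomials in
    u = 1 - c (computed as sin^2(theta)/(1 + c)), which are free of the
    catastrophic cancellation the raw forms suffer at small NA.
    """
    if not 0 < numerical_aperture < refractive_index:
        raise ConfigError(
            "numerical aperture must satisfy 0 < NA < refractive index "
            f"(got NA={numerical_aperture}, n={refractive_index})"
        )
    s2 = (numerical_aperture / refractive_index) ** 2
    c = np.sqrt(1.0 - s2)
    u = s2 / (1.0 + c)  # 1 - cos(theta), cancellation-free
    ka = u**2 * (3.0 - u) / 3.0
    kb = u * (8.0 - 4.0 * u + u**2) / 4.0
    kc = u**3 / 12.0
    return float(ka), float(kb), float(kc)


@dataclass(frozen=True)
class OpticsConfig:
    """Instrument state: G factor plus objective NA / immersion index.

    ka, kb, kc are derived deterministically from (NA, index); passing them
    explicitly is allowed only for serialization round-trips and is checked
    against recomputation.
    """

    g_factor: float = 1.0
    numerical_aperture: float = 1.3
    refractive_index: float = 1.518
    ka: float | None = None
    kb: float | None = None
    kc: float | None = None

    def __post_init__(self) -> None:
        if self.g_factor <= 0:
            raise ConfigError("g_factor must be positive")
        ka, kb, kc = compute_na_factors(self.numerical_aperture, self.refractive_index)
        for name, given, computed in (("ka", self.ka, ka), ("kb", self.kb, kb), ("kc", self.kc, kc)):
            if given is not None and abs(given - computed) > 1e-9:
                raise ConfigError(
                    f"stored {name}={given} inconsistent with NA/index (expected {computed})"
                )
        object.__setattr__(self, "ka", ka)
        object.__setattr__(self, "kb", kb)
        object.__setattr__(self, "kc", kc)


def na_mixing_matrix(optics: OpticsConfig) -> np.ndarray:
    """Forward channel-mixing matrix M of the objective, normalized so M -> I as NA -> 0.

    For emission excited by linearly polarized light the out-of-plane dipole
    component matches the perpendicular in-plane one, so the observed pair is

        [I_par_obs ]   1  [Kb       Ka + Kc] [I_par_true ]
        [I_perp_obs] = -- [Kc       Ka + Kb] [I_perp_true]
                       Kb

    (normalization by Kb leaves anisotropy unchanged and makes the paraxial
    limit the identity on intensities).
    """
    ka, kb, kc = optics.ka, optics.kb, optics.kc
    return np.array([[kb, ka + kc], [kc, ka + kb]]) / kb


@dataclass(frozen=True)
class PreprocessConfig:
    """Background estimate and intensity-range threshold fractions.

    ``background`` is either a scalar offset applied to both channels, a
    (parallel, perpendicular) pair of scalars, or a reference-region
    descriptor ``(row0, row1, col0, col1)`` whose per-channel mean is used.
    ``lower_fraction``/``upper_fraction`` exclude that fraction of the
    min-max intensity *range* at each end (default 0.05 each); set
    ``threshold_mode='quantile'`` to use distribution percentiles instead.
    """

    background: float | tuple = 0.0
    lower_fraction: float = 0.05
    upper_fraction: float = 0.05
    threshold_mode: str = "range"

    def __post_init__(self) -> None:
        if self.lower_fraction < 0 or self.upper_fraction < 0:
            raise ConfigError("threshold fractions must be non-negative")
        if self.lower_fraction + self.upper_fraction >= 1:
            raise ConfigError("threshold fractions must sum to < 1")
        if self.threshold_mode not in ("range", "quantile"):
            raise ConfigError("threshold_mode must be 'range' or 'quantile'")


@dataclass(frozen=True)
class AnisotropyMap:
    """Per-pixel anisotropy with the validity mask that produced it."""

    r: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if r.shape != mask.shape:
            raise ConfigError("r and mask shapes differ")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "mask", mask)

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def mean(self) -> float:
        if self.n_valid == 0:
            raise DegenerateDataError("no valid pixels to average")
        return float(self.r[self.mask].mean())


def _background_per_channel(
    frame: PolarizedFrame, background: float | tuple
) -> tuple[float, float]:
    if np.isscalar(background):
        b = float(background)
        if b < 0:
            raise ConfigError("scalar background must be non-negative")
        return b, b
    background = tuple(background)
    if len(background) == 2:
        bp, bq = float(background[0]), float(background[1])
        if bp < 0 or bq < 0:
            raise ConfigError("per-channel background must be non-negative")
        return bp, bq
    if len(background) == 4:
        r0, r1, c0, c1 = (int(v) for v in background)
        h, w = frame.shape
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ConfigError("reference region lies outside the frame or is empty")
        return (
            float(frame.parallel[r0:r1, c0:c1].mean()),
            float(frame.perpendicular[r0:r1, c0:c1].mean()),
        )
    raise ConfigError("background must be scalar, (par, perp) pair, or region tuple")


def subtract_background(frame: PolarizedFrame, cfg: PreprocessConfig) -> PolarizedFrame:
    """Subtract the per-channel background; clamp negatives to zero and flag them.

    Flagged pixels are carried on the frame and excluded by every later mask.
    """
    bp, bq = _background_per_channel(frame, cfg.background)
    par = np.asarray(frame.parallel, dtype=float)
    perp = np.asarray(frame.perpendicular, dtype=float)
    if bp >= par.max() and bq >= perp.max() and (bp > 0 or bq > 0):
        raise DegenerateDataError("background exceeds both channels everywhere")
    par_s = par - bp
    perp_s = perp - bq
    clipped = (par_s < 0) | (perp_s < 0)
    excluded = clipped if frame.excluded is None else (clipped | frame.excluded)
    return frame.replace(
        parallel=np.clip(par_s, 0, None),
        perpendicular=np.clip(perp_s, 0, None),
        excluded=excluded,
    )


def threshold_range(
    frame: PolarizedFrame, cfg: PreprocessConfig, g_factor: float = 1.0
) -> np.ndarray:
    """Mask keeping pixels inside the central band of the total-intensity range.

    Total intensity t = I_par + 2*G*I_perp is used so a pixel is kept or
    dropped in both channels jointly.  In 'range' mode the band is
    [t_min + lf*(t_max - t_min), t_max - uf*(t_max - t_min)]; in 'quantile'
    mode the lf/uf quantiles of the t distribution bound the band.  Pixels
    flagged during background subtraction are always excluded.
    """
    t = np.asarray(frame.parallel, dtype=float) + 2.0 * g_factor * np.asarray(
        frame.perpendicular, dtype=float
    )
    tmin, tmax = float(t.min()), float(t.max())
    if tmax == tmin:
        raise DegenerateDataError("flat frame: intensity range is zero")
    if cfg.threshold_mode == "range":
        lo = tmin + cfg.lower_fraction * (tmax - tmin)
        hi = tmax - cfg.upper_fraction * (tmax - tmin)
    else:
        lo = float(np.quantile(t, cfg.lower_fraction))
        hi = float(np.quantile(t, 1.0 - cfg.upper_fraction))
    mask = (t >= lo) & (t <= hi)
    if frame.excluded is not None:
        mask &= ~frame.excluded
    return mask


def estimate_g_factor(cal: CalibrationPair, tolerance: float = 0.05) -> float:
    """Estimate the G factor from an isotropic dye imaged with/without a half-wave plate.

    The without-plate channel ratio R0 = <I_par>/<I_perp> carries the detector
    bias times any residual sample polarization; swapping the polarizations
    with the plate gives R1 with the sample part inverted, so

        G = sqrt(R0 * R1)

    cancels the sample exactly and returns the pure detection-path bias.
    Warns if the two ratios disagree beyond ``tolerance`` (miscalibration).
    """
    import warnings

    means = {}
    for name, f in (("with", cal.with_hwp), ("without", cal.without_hwp)):
        mp = float(np.asarray(f.parallel, dtype=float).mean())
        mq = float(np.asarray(f.perpendicular, dtype=float).mean())
        if mp <= 0 or mq <= 0:
            raise DegenerateDataError(
                f"calibration frame ({name} plate) has non-positive channel mean"
            )
        means[name] = (mp, mq)
    r_without = means["without"][0] / means["without"][1]
    r_with = means["with"][0] / means["with"][1]
    g = float(np.sqrt(r_without * r_with))
    if abs(r_without - r_with) / g > tolerance:
        warnings.warn(
            "with/without-plate ratios disagree by more than "
            f"{tolerance:.0%}: possible miscalibration or anisotropic sample",
            stacklevel=2,
        )
    return g


def apply_na_correction(frame: PolarizedFrame, optics: OpticsConfig) -> PolarizedFrame:
    """Invert the high-NA channel mixing on a background-subtracted frame.

    The objective mixes the true polarized components before the detection
    path divides the perpendicular channel by G, so the inverse is applied in
    the gain-corrected domain: diag(1, 1/G) M^-1 diag(1, G).  The operation
    is linear and, for valid NA < n, always invertible; in the NA -> 0 limit
    it is the identity.
    """
    m = na_mixing_matrix(optics)
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if abs(det) < 1e-12:
        raise DegenerateDataError("singular NA correction matrix")
    minv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
    g = optics.g_factor
    par = np.asarray(frame.parallel, dtype=float)
    perp = np.asarray(frame.perpendicular, dtype=float) * g
    par_c = minv[0, 0] * par + minv[0, 1] * perp
    perp_c = (minv[1, 0] * par + minv[1, 1] * perp) / g
    return frame.replace(parallel=par_c, perpendicular=perp_c)


def compute_anisotropy(
    frame: PolarizedFrame, optics: OpticsConfig, mask: np.ndarray
) -> AnisotropyMap:
    """Per-pixel r = (I_par - G I_perp)/(I_par + 2 G I_perp) on masked pixels.

    Pixels whose denominator is non-positive are dropped from the mask;
    an empty mask after that guard is a degenerate input.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise ConfigError("mask shape does not match frame")
    g = optics.g_factor
    par = np.asarray(frame.parallel, dtype=float)
    perp = np.asarray(frame.perpendicular, dtype=float)
    denom = par + 2.0 * g * perp
    valid = mask & (denom > 0)
    if frame.excluded is not None:
        valid &= ~frame.excluded
    if not valid.any():
        raise DegenerateDataError("no valid pixels after denominator guard")
    r = np.full(frame.shape, np.nan)
    r[valid] = (par[valid] - g * perp[valid]) / denom[valid]
    return AnisotropyMap(r=r, mask=valid)


def normalize_anisotropy(r_apollo: float, r_r198p: float, r_tdimer: float) -> float:
    """Normalize a sensor anisotropy by the control dynamic range.

    r_norm = r_sensor / (r_monomer_control - r_dimer_control); the monomer
    control must sit above the dimer control or the controls have failed.
    """
    dynamic_range = r_r198p - r_tdimer
    if dynamic_range <= 0:
        raise ConfigError(
            "monomer control anisotropy must exceed dimer control "
            f"(got {r_r198p} vs {r_tdimer})"
        )
    return r_apollo / dynamic_range


def median_filter_for_display(r: np.ndarray, size: int = 3) -> np.ndarray:
    """Median-filtered copy of an anisotropy image, for visual display only.

    Never applied before quantification.
    """
    filled = np.nan_to_num(r, nan=0.0)
    return ndimage.median_filter(filled, size=size)
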