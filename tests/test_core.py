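import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from anisopipe import (
    CalibrationPair,
    ImagingParams,
    OpticsConfig,
    PolarizedFrame,
    PreprocessConfig,
    apply_na_correction,
    compute_anisotropy,
    compute_na_factors,
    estimate_g_factor,
    normalize_anisotropy,
    render_calibration_pair,
    subtract_background,
    threshold_range,
)
from anisopipe.core import na_mixing_matrix
from anisopipe.errors import ConfigError, DegenerateDataError

from conftest import uniform_frame


# ---------------------------------------------------------------- background
def test_scalar_background_is_a_constant_shift():
    frame = uniform_frame(100, 100)
    out = subtract_background(frame, PreprocessConfig(background=30.0))
    assert np.all(out.parallel == 70) and np.all(out.perpendicular == 70)


def test_zero_background_is_identity():
    frame = uniform_frame(55, 41)
    out = subtract_background(frame, PreprocessConfig(background=0.0))
    np.testing.assert_array_equal(out.parallel, frame.parallel)
    assert not out.excluded.any()


def test_region_background_equals_scalar_of_region_mean(rng):
    par = rng.uniform(20, 200, (16, 16))
    perp = rng.uniform(20, 200, (16, 16))
    # plant a reference region with known mean 12.5 in both channels
    par[:4, :4] = perp[:4, :4] = 12.5
    frame = PolarizedFrame(par, perp)
    by_region = subtract_background(
        frame, PreprocessConfig(background=(0, 4, 0, 4))
    )
    # oracle: direct per-pixel arithmetic with the scalar 12.5
    np.testing.assert_allclose(by_region.parallel, np.clip(par - 12.5, 0, None))
    np.testing.assert_allclose(by_region.perpendicular, np.clip(perp - 12.5, 0, None))


def test_negative_pixels_are_clamped_and_flagged():
    par = np.full((4, 4), 100.0)
    par[0, 0] = 5.0
    frame = PolarizedFrame(par, np.full((4, 4), 100.0))
    out = subtract_background(frame, PreprocessConfig(background=30.0))
    assert out.parallel[0, 0] == 0.0
    assert out.excluded[0, 0] and out.excluded.sum() == 1
    mask = threshold_range(out, PreprocessConfig(lower_fraction=0, upper_fraction=0))
    assert not mask[0, 0]


def test_background_above_everything_is_degenerate():
    with pytest.raises(DegenerateDataError):
        subtract_background(uniform_frame(10, 10), PreprocessConfig(background=50.0))


# ---------------------------------------------------------------- threshold
def test_range_threshold_keeps_central_band():
    totals = np.arange(0.0, 101.0, 10.0)  # 0, 10, ..., 100
    frame = PolarizedFrame(totals.reshape(1, -1), np.zeros((1, 11)))
    cfg = PreprocessConfig(lower_fraction=0.05, upper_fraction=0.05)
    mask = threshold_range(frame, cfg, g_factor=1.0)
    kept = totals[mask[0]]
    assert kept.min() == 10 and kept.max() == 90  # band is [5, 95]


def test_zero_fractions_keep_all_pixels(rng):
    frame = PolarizedFrame(rng.uniform(1, 9, (8, 8)), rng.uniform(1, 9, (8, 8)))
    mask = threshold_range(
        frame, PreprocessConfig(lower_fraction=0, upper_fraction=0)
    )
    assert mask.all()


def test_range_threshold_matches_brute_force_pixel_loop(rng):
    g = 1.2
    par = rng.uniform(0, 500, (12, 12))
    perp = rng.uniform(0, 500, (12, 12))
    frame = PolarizedFrame(par, perp)
    cfg = PreprocessConfig(lower_fraction=0.05, upper_fraction=0.05)
    mask = threshold_range(frame, cfg, g_factor=g)
    t = par + 2 * g * perp
    lo = t.min() + 0.05 * (t.max() - t.min())
    hi = t.max() - 0.05 * (t.max() - t.min())
    for i in range(12):
        for j in range(12):
            assert mask[i, j] == (lo <= t[i, j] <= hi)


def test_quantile_threshold_mode(rng):
    par = rng.uniform(0, 500, (20, 20))
    frame = PolarizedFrame(par, np.zeros_like(par))
    cfg = PreprocessConfig(
        lower_fraction=0.1, upper_fraction=0.1, threshold_mode="quantile"
    )
    mask = threshold_range(frame, cfg)
    # ~80% of pixels survive under the distribution-percentile interpretation
    assert 0.75 <= mask.mean() <= 0.85


def test_flat_frame_is_degenerate():
    with pytest.raises(DegenerateDataError):
        threshold_range(uniform_frame(5, 5), PreprocessConfig())


# ---------------------------------------------------------------- G factor
def test_unbiased_system_gives_unit_g():
    cal = CalibrationPair(
        with_hwp=uniform_frame(100, 100), without_hwp=uniform_frame(100, 100)
    )
    assert estimate_g_factor(cal) == pytest.approx(1.0)


def test_detection_bias_recovered_exactly_noiseless():
    # perpendicular path attenuated to 0.8 => true G = 1/0.8 = 1.25;
    # ideal plate swaps the (isotropic) components upstream of the bias
    cal = CalibrationPair(
        with_hwp=uniform_frame(300, 300 * 0.8),
        without_hwp=uniform_frame(300, 300 * 0.8),
    )
    assert estimate_g_factor(cal) == pytest.approx(1.25, abs=1e-6)


def test_residual_sample_anisotropy_cancels_in_the_two_image_product():
    # sample with residual polarization s != 1: without-plate ratio s*G,
    # with-plate ratio G/s; the geometric mean recovers G exactly
    g_true, s = 1.25, 1.1
    cal = CalibrationPair(
        without_hwp=uniform_frame(100 * s, 100 / g_true),
        with_hwp=uniform_frame(100, 100 * s / g_true),
    )
    with pytest.warns(UserWarning, match="disagree"):
        g = estimate_g_factor(cal, tolerance=0.01)
    assert g == pytest.approx(g_true, rel=1e-9)


@pytest.mark.parametrize("g_true", [0.8, 1.0, 1.25])
def test_g_recovery_under_poisson_noise(g_true):
    errs = []
    for seed in range(20):
        imaging = ImagingParams(
            photons_per_pixel=3e4,  # ~1e4 expected counts per channel pixel
            g_factor_true=g_true,
            poisson_noise=True,
            seed=seed,
        )
        cal = render_calibration_pair(imaging, shape=(64, 64))
        errs.append(abs(estimate_g_factor(cal) - g_true) / g_true)
    assert max(errs) < 0.01


def test_nonpositive_calibration_mean_rejected():
    cal = CalibrationPair(
        with_hwp=uniform_frame(0, 100), without_hwp=uniform_frame(100, 100)
    )
    with pytest.raises(DegenerateDataError):
        estimate_g_factor(cal)


# ---------------------------------------------------------------- NA factors
def na_factors_by_quadrature(na, n):
    """Independent oracle: numerically integrate the dipole far-field
    projection over the collection cone for each dipole orientation."""
    theta_max = np.arcsin(na / n)

    def coeff(weight):
        val, _ = integrate.dblquad(
            lambda phi, th: weight(th, phi) * np.sin(th),
            0.0,
            theta_max,
            0.0,
            2 * np.pi,
            epsabs=1e-12,
            epsrel=1e-12,
        )
        return val / np.pi

    # x-analyzer field component for dipoles along x, y, z
    ex_x = lambda th, phi: (np.cos(th) * np.cos(phi) ** 2 + np.sin(phi) ** 2) ** 2
    ex_y = lambda th, phi: ((np.cos(th) - 1) * np.sin(phi) * np.cos(phi)) ** 2
    ex_z = lambda th, phi: (np.sin(th) * np.cos(phi)) ** 2
    kb = coeff(ex_x)
    kc = coeff(ex_y)
    ka = coeff(ex_z)
    return ka, kb, kc


def test_na_factors_match_adaptive_quadrature():
    ka, kb, kc = compute_na_factors(1.3, 1.518)
    ka_q, kb_q, kc_q = na_factors_by_quadrature(1.3, 1.518)
    assert abs(ka - ka_q) < 1e-8
    assert abs(kb - kb_q) < 1e-8
    assert abs(kc - kc_q) < 1e-8


def test_paraxial_limit_makes_correction_identity():
    optics = OpticsConfig(numerical_aperture=1e-4, refractive_index=1.518)
    m = na_mixing_matrix(optics)
    np.testing.assert_allclose(m, np.eye(2), atol=1e-8)


def test_correction_magnitude_grows_with_na():
    def off_diag(na):
        m = na_mixing_matrix(
            OpticsConfig(numerical_aperture=na, refractive_index=1.518)
        )
        return abs(m - np.eye(2)).sum()

    assert off_diag(1.0) > off_diag(0.5) > 0


def test_na_must_stay_below_index():
    with pytest.raises(ConfigError):
        compute_na_factors(1.6, 1.518)


# ---------------------------------------------------------------- correction
def test_forward_mix_then_correct_recovers_true_pair():
    optics = OpticsConfig(
        g_factor=1.0, numerical_aperture=1.3, refractive_index=1.518
    )
    m = na_mixing_matrix(optics)
    true = np.array([300.0, 100.0])
    mixed = m @ true
    frame = uniform_frame(mixed[0], mixed[1], shape=(4, 4))
    out = apply_na_correction(frame, optics)
    np.testing.assert_allclose(out.parallel, 300.0, atol=1e-9)
    np.testing.assert_allclose(out.perpendicular, 100.0, atol=1e-9)


def test_correction_is_linear():
    optics = OpticsConfig(numerical_aperture=1.3, refractive_index=1.518)
    f1 = uniform_frame(120, 80)
    f2 = uniform_frame(240, 160)
    out1, out2 = apply_na_correction(f1, optics), apply_na_correction(f2, optics)
    np.testing.assert_allclose(out2.parallel, 2 * out1.parallel, rtol=1e-12)
    np.testing.assert_allclose(out2.perpendicular, 2 * out1.perpendicular, rtol=1e-12)


def test_small_na_leaves_anisotropy_essentially_unchanged(rng):
    optics = OpticsConfig(numerical_aperture=0.05, refractive_index=1.518)
    par = rng.uniform(100, 400, (10, 10))
    perp = rng.uniform(50, 200, (10, 10))
    frame = PolarizedFrame(par, perp)
    mask = np.ones((10, 10), bool)
    r_raw = compute_anisotropy(frame, optics, mask).r
    r_corr = compute_anisotropy(apply_na_correction(frame, optics), optics, mask).r
    assert np.nanmax(np.abs(r_raw - r_corr)) < 1e-3


# ---------------------------------------------------------------- anisotropy
@pytest.mark.parametrize(
    "par,perp,g,expected",
    [
        (1.0, 1.0, 1.0, 0.0),
        (3.0, 1.0, 1.0, 0.4),
        (3.0, 1.0, 2.0, 1.0 / 7.0),
    ],
)
def test_anisotropy_closed_form(par, perp, g, expected):
    optics = OpticsConfig(g_factor=g, numerical_aperture=0.01)
    amap = compute_anisotropy(
        uniform_frame(par, perp), optics, np.ones((8, 8), bool)
    )
    np.testing.assert_allclose(amap.r, expected)
    assert amap.n_valid == 64


def test_formula_matches_scalar_arithmetic_per_pixel(rng):
    g = 1.37
    par = rng.uniform(1, 1000, (20, 20))
    perp = rng.uniform(1, 1000, (20, 20))
    optics = OpticsConfig(g_factor=g, numerical_aperture=0.01)
    amap = compute_anisotropy(PolarizedFrame(par, perp), optics, np.ones((20, 20), bool))
    for i in range(20):
        for j in range(20):
            expect = (par[i, j] - g * perp[i, j]) / (par[i, j] + 2 * g * perp[i, j])
            assert amap.r[i, j] == expect


def test_nonpositive_denominator_pixels_are_dropped():
    par = np.full((4, 4), 10.0)
    par[1, 1] = 0.0
    perp = np.full((4, 4), 5.0)
    perp[1, 1] = 0.0
    amap = compute_anisotropy(
        PolarizedFrame(par, perp), OpticsConfig(numerical_aperture=0.01), np.ones((4, 4), bool)
    )
    assert not amap.mask[1, 1] and amap.n_valid == 15
    assert np.isnan(amap.r[1, 1])


def test_empty_mask_is_degenerate():
    with pytest.raises(DegenerateDataError):
        compute_anisotropy(
            uniform_frame(10, 10),
            OpticsConfig(numerical_aperture=0.01),
            np.zeros((8, 8), bool),
        )


@settings(max_examples=25, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_anisotropy_is_scale_invariant(scale):
    optics = OpticsConfig(g_factor=1.25, numerical_aperture=1.3)
    base = compute_anisotropy(
        uniform_frame(320, 140), optics, np.ones((8, 8), bool)
    ).r
    scaled = compute_anisotropy(
        uniform_frame(320 * scale, 140 * scale), optics, np.ones((8, 8), bool)
    ).r
    np.testing.assert_allclose(scaled, base, rtol=1e-9)


def test_calibration_closure_noiseless_and_noisy():
    # noiseless: r of the calibration sample with the estimated G is ~0
    imaging = ImagingParams(photons_per_pixel=3e4, g_factor_true=1.25, poisson_noise=False)
    cal = render_calibration_pair(imaging)
    g = estimate_g_factor(cal)
    optics = OpticsConfig(g_factor=g, numerical_aperture=0.01)
    r0 = compute_anisotropy(
        cal.without_hwp, optics, np.ones(cal.without_hwp.shape, bool)
    ).mean()
    assert abs(r0) < 1e-6
    # Poisson at ~1e4 counts/pixel: closure within 1e-2
    noisy = render_calibration_pair(
        ImagingParams(photons_per_pixel=3e4, g_factor_true=1.25, seed=11)
    )
    gn = estimate_g_factor(noisy)
    rn = compute_anisotropy(
        noisy.without_hwp,
        OpticsConfig(g_factor=gn, numerical_aperture=0.01),
        np.ones(noisy.without_hwp.shape, bool),
    ).mean()
    assert abs(rn) < 1e-2


# ---------------------------------------------------------------- normalize
def test_dynamic_range_normalization():
    assert normalize_anisotropy(0.3, 0.4, 0.2) == pytest.approx(1.5)
    assert normalize_anisotropy(0.0, 0.4, 0.2) == 0.0
    with pytest.raises(ConfigError):
        normalize_anisotropy(0.3, 0.2, 0.2)
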