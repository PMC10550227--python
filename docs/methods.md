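# Methods

## Anisotropy model

A fluorophore population excited by linearly polarized (two-photon) light
emits with intensities `I∥` and `I⊥` parallel and perpendicular to the
excitation polarization. The steady-state anisotropy
`r = (I∥ − G·I⊥)/(I∥ + 2·G·I⊥)` is computed per pixel, where `G` corrects
the unequal detection efficiency of the two channels. Algebraically
`r ∈ [−0.5, 1]`; under two-photon photoselection the physical ceiling is
`r₀ = 4/7 ≈ 0.571`, which the simulator enforces on its monomer bound.
homo-FRET between identical fluorophores depolarizes emission without
changing intensity or spectrum, so sensor dimerization reads out as a drop
in `r`.

### G factor

The calibration images an isotropic, fast-rotating dye (true `r = 0`) with
and without a half-wave plate in the emission path. With channel ratios
`R = ⟨I∥⟩/⟨I⊥⟩` for the two images, the estimator is
`G = sqrt(R_without · R_with)`. Under an ideal plate (exact polarization
swap upstream of the detection gains) any residual sample polarization
enters the two ratios with opposite sign and cancels exactly in the
product, leaving the pure detection-path bias. A warning is raised when the
two ratios disagree by more than 5% (miscalibration or an anisotropic
calibration sample). Closure is tested by recomputing the calibration
sample's anisotropy with the estimated `G`: zero to 1e-6 noiseless, to 1e-2
under Poisson noise at ~1e4 counts/pixel.

### High-NA correction

A high-NA objective collects a cone of half-angle `θ = arcsin(NA/n)` and
thereby mixes the polarized components. Integrating the projected dipole
far field over the cone gives the three classical aperture factors
(`c = cos θ`): `Ka = (2 − 3c + c³)/3`, `Kb = (5 − 3c − c² − c³)/4`,
`Kc = (1 − c)³/12`. Assuming the out-of-plane dipole component matches the
perpendicular in-plane one (valid for excitation-symmetric emission), the
observed pair is a 2×2 linear mixing

```
[I∥_obs ]      1  [Kb    Ka+Kc] [I∥_true ]
[I⊥_obs ]  =  ──  [Kc    Ka+Kb] [I⊥_true ]
              Kb
```

normalized by `Kb` so the paraxial limit is the identity. The correction
inverts this mixing; because the objective acts before the detection-path
gain, the inverse is applied in the gain-corrected domain
(`diag(1, 1/G)·M⁻¹·diag(1, G)`), keeping the stated operation order
(background → NA correction → `G` inside the `r` formula) an exact inverse
of the forward model. Numerically the factors are evaluated as polynomials
in `u = 1 − c` with `u = sin²θ/(1 + c)`; the raw cubic forms cancel
catastrophically below NA ≈ 1e-3. The closed forms are validated against
adaptive quadrature of the aperture integrals to 1e-8, and
forward-mix-then-correct is the identity to 1e-9.

### Preprocessing

Background is a scalar per channel or the mean of a user-specified
reference region; subtraction clamps negatives to zero and flags those
pixels out of all later masks. The intensity threshold keeps pixels whose
total `t = I∥ + 2·G·I⊥` lies within the central band of the min–max range,
excluding `lower_fraction`/`upper_fraction` (default 0.05 each) of the
range at each end; a distribution-percentile variant is available via
`threshold_mode="quantile"`. The mask is computed on the combined
intensity, never per channel, so a pixel is kept or dropped in both
channels jointly. Median filtering exists only for display and is never
applied before quantification.

## Assay quantification

Time series are reduced per time point to the mean anisotropy of all valid
pixels; z-stacks are pooled over all valid pixels of slices retaining at
least 1000 pixels after preprocessing (edge slices with few surviving
pixels would otherwise dominate their own mean). Phases are fitted
separately: baseline as a constant; oxidation and recovery each as
`plateau + A·exp(−k·(t − t₀))` by least squares with restarted initial
guesses. Half-lives are `ln 2 / k` of the fitted rate — i.e. the time to
cover half the fitted asymptotic amplitude — which for first-order
kinetics is sampling-rate independent; a raw-sample variant
(`raw_half_life`: first linear-interpolated crossing of half the observed
phase change) is reported alongside for robustness. Endpoint differences
(drop, baseline change) are read from the fits at the phase boundaries by
default, so a single noisy 10-s sample never defines a metric
(`use_fitted_endpoints=False` restores literal differencing). A half-life
is reported as undefined when the realized fitted change across the phase
window is below a noise floor (default 2× the baseline residual SD); the
realized in-window change is used rather than the asymptotic amplitude
because a near-zero-rate fit can carry an arbitrarily large amplitude
while modeling a flat drift.

## Forward simulator

The generator emulates the in vivo assay conditions: an elliptical
islet-shaped phantom tiled into Voronoi-like cells with lognormal per-cell
sensor expression (log-SD 0.3); first-order NADPH oxidation during oxidant
perfusion and first-order recovery after washout, as piecewise closed
forms continuous at the phase boundaries (0–5 / 5–10 / 10–20 min, 10-s
sampling); a Hill-form dimerization response to absolute NADP⁺; an
intensity-weighted anisotropy mixture with dimer brightness 2× (two
fluorophores per dimer), exact for steady-state anisotropy additivity;
depth-proportional replacement of polarized photons by fully depolarized
scatter, `r_obs = (1 − α·depth)·r_true`, the simplest model reproducing
the downward skew of absolute anisotropy with depth while scaling the
control separation by the same factor; and image formation with forward
high-NA mixing, perpendicular-channel gain `1/G`, additive camera offset
and Poisson sampling. All randomness flows from a single seed;
equal-seeded runs are bit-identical.

### Default study conditions and why

| parameter | default | rationale |
|---|---|---|
| r_mono / r_dimer | 0.40 / 0.20 | plausible two-photon control bounds below the 4/7 ceiling |
| k_ox, k_red | ln2/60 s⁻¹, ln2/300 s⁻¹ | depletion plateaus within the 5-min oxidant phase; recovery re-equilibrates within ~10 min |
| nadph_frac0, equilibrium_frac | 0.9 | highly reduced basal pool (well-fed embryo) |
| k_half | 50 (pool-fraction units) | sensor far from saturation; see below |
| hill | 1 | no cooperativity assumed |
| photons_per_pixel | 20000 | bright expression on a 16-bit photon-counting detector |
| background_counts | 50 | small camera offset |
| g_factor_true | 1.25 | realistic channel imbalance |
| NA / n | 1.3 / 1.518 | 40× oil-immersion objective |
| scatter_alpha_per_um | 0.004 | ~16% depolarization at 40 µm depth |
| phantom | 80×80 px, 30 cells, 0.6 µm/px | ~45-µm embryonic islet slice |
| imaging depth (time series) | 12 µm | first quarter of the islet |

The `k_half` default is a deliberate design point: interpreting trace
half-lives as NADPH-pool kinetics presumes the sensor readout is
proportional to the NADPH fraction. That holds only in the sub-saturation
(pseudo-linear) regime of the Hill response; near half-saturation the
anisotropy trace is visibly non-exponential and its fitted rate no longer
equals the pool rate (at `k_half = 0.5` the apparent depletion half-life
is ~25 s for a true 60 s). With `k_half = 50` the residual transfer
nonlinearity biases fitted half-lives by ≲ 2.5% (depletion) and ≲ 4%
(recovery) noiselessly, and a 20-embryo cohort at the default photon
budget recovers both half-lives with median absolute relative error of a
few percent. Pool expansion (`pool_scale`, modeling stress-activated NAD⁺
kinase) ramps in linearly over the recovery phase — a constant scale would
cancel between the 5- and 20-min points — so `pool_scale > 1` lowers the
20-min baseline relative to 5 min.

### What the generator does not emulate

No optical PSF or pixel cross-talk; no detector read noise (Poisson only);
no photobleaching or motion; no sub-cellular structure or cell-level
heterogeneity in redox state (expression varies per cell, kinetics do
not); scatter is a scalar depolarization, not a wavelength- or
angle-dependent process. Passing tests therefore demonstrate correctness
of the computational chain and its statistical behaviour under photon
noise — not robustness to motion artefacts, bleaching or segmentation
error in real acquisitions.

## Numerical choices

Phase fits bound the rate to `k ≥ 1e-8 s⁻¹` and retry from three initial
guesses before declaring non-convergence. Flat frames (zero intensity
range), empty masks, non-positive calibration means and `NA ≥ n` raise
typed errors that the CLI maps to exit codes 2/3/4. Boundary samples at
5 and 10 min belong to both adjacent phases. The problem sizes used
throughout the tests and the acceptance script (80×80 phantoms, 121-point
traces, 20-embryo cohorts) are the package's default study scale; they
keep every check comfortably reproducible on a single CPU.

## Known limitations

The aperture factors assume an aplanatic objective without apodization and
an emission dipole distribution symmetric about the excitation axis; both
are the standard assumptions behind the three-factor correction. The
G-factor estimator assumes an ideal half-wave plate. The half-life
noise-floor default (2× baseline residual SD) is heuristic. Real
acquisitions with drifting background or saturating pixels need the
region-based background estimate and the quantile threshold mode rather
than the defaults.
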