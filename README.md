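# anisopipe

Steady-state fluorescence **anisotropy imaging pipeline** for homo-FRET
biosensors, built around the NADP⁺-driven monomer/homodimer sensor
(Apollo-NADP⁺-style) as used to follow NADPH/NADP⁺ redox dynamics in
pancreatic β cells of live zebrafish embryos. It is aimed at microscopists
who acquire paired polarized emission channels (two-photon excitation, a
polarizing beamsplitter, one detector pathway per polarization) and want a
tested, scriptable route from raw TIFF stacks to per-pixel anisotropy maps
and kinetic assay numbers — plus a forward simulator that makes every stage
of that route verifiable against known ground truth.

## The measurement

Per pixel, the steady-state anisotropy is

```
r = (I∥ − G·I⊥) / (I∥ + 2·G·I⊥)
```

where `G` is the instrument factor balancing the two detection paths,
estimated from an isotropic dye imaged with and without a half-wave plate
(`G = sqrt(R_without · R_with)`, which cancels residual sample
polarization). Before the formula is applied, each frame is
background-subtracted and corrected for the polarization mixing introduced
by a high-NA objective using the classical aperture-integral factors (with
`θ = arcsin(NA/n)`, `c = cos θ`):

```
Ka = (2 − 3c + c³)/3,  Kb = (5 − 3c − c² − c³)/4,  Kc = (1 − c)³/12
```

which define an invertible 2×2 mixing of the true polarized components.
Pixels are masked by a threshold on the upper and lower 5% of the min–max
range of total intensity `I∥ + 2·G·I⊥`.

## The assay

A transient-oxidation time series (10-s sampling) has three phases:
baseline (0–5 min), oxidant perfusion (5–10 min), washout recovery
(10–20 min). Whole-islet z-stacks (1-µm steps) are pooled over slices
retaining ≥ 1000 valid pixels. Each time series is reduced to four numbers:
the oxidant-induced drop `r(10 min) − r(5 min)`, the depletion half-life
`ln 2 / k_ox` from a falling-exponential fit, the recovery half-life
`ln 2 / k_red` from a rising-exponential fit, and the baseline change
`r(20 min) − r(5 min)`. The forward simulator (`anisopipe.simulate`)
generates islet-shaped phantoms, first-order oxidation/recovery kinetics, a
Hill-form sensor response, depth-dependent scatter depolarization, high-NA
mixing, channel gain imbalance, camera offset and Poisson photon noise —
all seeded and bit-reproducible.

## Worked example

`examples/assay_config.yaml` simulates a default embryo (oxidation
half-life 60 s, recovery half-life 300 s, G = 1.25, NA 1.3, background 50
counts, Poisson noise) and runs the full pipeline on it:

```
$ anisopipe all --config examples/assay_config.yaml
INFO anisopipe: frame 0: 3789/6400 pixels survive preprocessing
...
INFO anisopipe: fits: baseline=0.38007 (sd 1.20e-04), depletion k=1.17495e-02 /s amp=6.54e-03, recovery k=2.13090e-03 /s amp=-6.50e-03
{
 "diamide_drop": -0.006342250781053715,
 "depletion_half_life_s": 58.99365565422462,
 "recovery_half_life_s": 325.28440246694083,
 "baseline_change": -0.001642819957005548
}
```

Reading the output: the baseline anisotropy sits at 0.380; the oxidant
drops it by 0.0063 (the sensor dimerizes as NADPH is oxidized); the fitted
depletion half-life of 59.0 s and recovery half-life of 325 s recover the
simulated ground truth of 60 s and 300 s to within the photon-noise limit;
the small negative baseline change reflects recovery that has not fully
re-equilibrated at 20 min. Outputs land in `assay_out/`: the simulated
stack and its ground truth, per-frame anisotropy maps and masks (TIFF),
`assay_trace.csv`, `assay_metrics.csv`, and a resolved-config provenance
file. The subcommands `simulate`, `gfactor`, `process` and `quantify` run
the stages separately; `quantify` on a z-stack input reports the pooled
whole-islet mean instead.

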