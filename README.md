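# ranoise

Noise analysis of retinoic-acid (RA) morphogen gradients in the vertebrate
hindbrain: phasor-FLIM relative-abundance estimation, gradient-shape
regression, spatial/temporal noise statistics, a stochastic
reaction–diffusion model of the RA signaling network, and a
segmentation-based sharpness index for rhombomere expression boundaries —
with seeded synthetic-data generators for every input class, so the whole
pipeline is testable without microscope data.

## Who this is for

Developmental biologists and biophysicists quantifying morphogen gradients
by fluorescence-lifetime imaging (FLIM), and modelers studying how
intracellular binding proteins (Crabp2a) and self-enhanced degradation
(Cyp26a1) shape the mean and the fluctuations of a gradient, and how
noise-induced switching of a bistable gene network (krox20 / hoxb1a)
sharpens segment boundaries.

## The statistics and the model

**Phasor transform.** A per-pixel photon-arrival histogram I(t) over one
laser period maps to a point at harmonic *n* of the repetition rate ω:

    g = Σ I(t_k) cos(nωt_k) / Σ I(t_k),   s = Σ I(t_k) sin(nωt_k) / Σ I(t_k)

Single-exponential decays of lifetime τ lie on the universal semicircle
(g − ½)² + s² = ¼; mixtures lie at the intensity-weighted combination of
their components. Because the plot has unit diameter, the Cartesian
distance d_RA from a measured point to the pure-RA reference yields a
relative-abundance statistic **1 − d_RA ∈ [0, 1]**. Linear unmixing,
photon shot-noise propagation, and cross-checking at a different harmonic
(3 × 80 MHz = 240 MHz) are included.

**Noise statistics.** Spatial noise is the maximum within-row residual
range (after each row's best gradient fit) as a percentage of the fitted
gradient amplitude. Temporal noise is the coefficient of variation of
12-s-sampled single-cell traces; the dominant fluctuation period is the
mean significant lag of a moving-window autocorrelation times the sampling
interval. Group variability is compared with Levene's test and a one-way
ANOVA of per-cell CVs.

**Stochastic model.** Cells on a 1-D anterior–posterior chain exchange
extracellular RA by diffusion from a posterior source; intracellular free
RA binds a Crabp2a-like buffer (complex half-life 1.7 min, so
k_off = ln 2 / 1.7 ≈ 0.408 min⁻¹) and is degraded by a Cyp26a1-like enzyme
induced by RA signaling (self-enhanced degradation). The bound complex
drives a mutually repressive krox20/hoxb1a-like toggle. Integration is
Euler–Maruyama with chemical-Langevin noise (system size ω is the single
noise dial). Under the calibrated defaults, scaling the buffer level
changes the *variability* of free RA at constant mean, scaling the enzyme
changes the *mean* at roughly constant variability, and turning noise up
100-fold widens the mixed zone at the gene-expression boundary instead of
letting it sharpen.

**Sharpness index.** For per-slice boundary traces, S = Σ d_sharp / Σ d_xy,
the ratio of the straight-line boundary length to the measured boundary
length summed over z-slices (slice thickness cancels); S = 1 is perfectly
sharp, a fine 45° sawtooth gives 1/√2.

## Worked example

```python
import numpy as np
from ranoise import flim_phasor as fp
from ranoise import synthetic_data as sd
from ranoise import noise_stats as ns

# a synthetic decay cube whose pixels are 60% RA / 40% autofluorescence
cube, truth = sd.make_flim_cube(np.full((32, 32), 0.6), photons=5000, config=42)
refs = fp.ReferenceSet(entries=(
    ("RA", fp.phasor_of_lifetime(0.35)),
    ("background", fp.phasor_of_lifetime(2.5)),
))
pt = fp.compute_phasor(cube)
est = fp.relative_abundance(pt, refs)
fr = fp.unmix(pt, refs)
print(f"region phasor: g = {pt.g:.4f}, s = {pt.s:.4f}")
print(f"d_RA = {est.d_ra:.4f}  ->  1 - d_RA = {est.one_minus_d:.4f}")
print(f"unmixed RA intensity fraction: {fr['RA']:.4f} (truth 0.6)")

# dominant fluctuation period of a 12-s-sampled trace
trace, _ = sd.make_temporal_trace(period_s=162.0, config=42)
ac = ns.movwin_autocorr(trace)
print(f"significant lags: {ac.significant_lags}  ->  "
      f"period {ac.period:.0f} s = {ac.period/60:.1f} min")
```

prints

```
region phasor: g = 0.7372, s = 0.2972
d_RA = 0.2650  ->  1 - d_RA = 0.7350
unmixed RA intensity fraction: 0.6002 (truth 0.6)
significant lags: (11, 12, 13, 14, 15, 16)  ->  period 162 s = 2.7 min
```

The measured phasor sits between the pure-RA and background anchors; its
distance to the RA anchor gives the relative abundance 0.735, and linear
unmixing recovers the generating RA fraction to three decimals. The
autocorrelation of the fluctuation trace flags the lag cluster around
13–14 (162 s / 12 s = 13.5), recovering the built-in 2.7-min period.

A full end-to-end run on synthetic data (every stage, with a manifest and
a markdown report):

```bash
ranoise run --seed 1 --out demo_run
ranoise report --manifest demo_run/manifest.json
```

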