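# Methods

This note documents the models, estimators, calibrations, and numerical
choices behind `ranoise`, in the order the pipeline uses them.

## Phasor-FLIM relative abundance

A decay cube holds per-pixel photon-arrival histograms over one laser
period (rep rate in MHz; bin width × bin count equals the period to 1e-9
relative tolerance). The phasor transform uses bin *centers*
t_k = (k + ½)·Δt; the midpoint rule minimizes discretization bias, and for
a periodically wrapped single exponential the discrete (g, s) agree with
the closed form (1, nωτ)/(1 + (nωτ)²) to better than 5e-3 at 256 bins.
Region phasors pool photons over the mask *before* transforming (a
per-pixel map is available separately); this weights pixels by brightness,
which is the right behavior for a ratio-of-sums estimator.

No instrument-response deconvolution is performed: reference species
(fluorescein, rhodamine, pure RA) measured through the same pipeline
anchor the coordinate frame, so all positions are relative to calibrated
references. The pure-RA anchor defaults to a 0.35-ns synthetic decay —
a plausible short autofluorescence lifetime placing it in the high-g,
low-s corner — and is configurable; it is a modeling choice, not a
measured value. A reference set validates that its RA entry actually sits
in that corner.

The relative abundance is 1 − d_RA with d_RA the Euclidean distance to
the RA anchor. Because the universal circle has unit diameter, physical
points give values in [0, 1]; measurement noise can push d_RA slightly
above 1, in which case the statistic is clipped at 0 with a logged
warning rather than reported negative.

Unmixing solves min ‖Σ fᵢPᵢ − m‖² s.t. Σfᵢ = 1, fᵢ ≥ 0 by exhaustive
active-set enumeration (exact for ≤ 3 species), with ties broken toward
the minimal-norm solution so output is deterministic. Coincident or
collinear references raise a degeneracy error; points outside the
reference hull are unmixed with a large-residual warning (threshold 0.05
phasor units).

Shot noise is propagated by the delta method: for bin probabilities p_k
and N expected photons, Var(g) = Σ p_k (cos nωt_k − g)² / N, so the bound
scales exactly as N^(−1/2). The default evaluation shape is a wrapped
exponential at the semicircle midpoint (nωτ = 1), a representative
near-worst case; callers can pass their own decay. Monte-Carlo Poisson
resampling validates the bound to within 10% at N = 10⁴ in the tests.

## Gradient-shape regression

Four shapes are fit by OLS to abundance-vs-position profiles: linear
(a + bx), quadratic (a + bx + cx²), quadratic without the linear term
(a + cx²), and exponential. The exponential is fit as a *log-linear* OLS
(log-abundance on position) with the amplitude back-transformed; over the
shallow dynamic range of the measured gradients the log is nearly affine,
which is exactly why the shapes are hard to distinguish. Consequences:
the exponential's adjusted R² and F-test refer to the log-scale
regression, and non-positive abundances are a domain error (offending
positions are named).

`compare_fits` declares a gradient present when the linear slope is
significantly positive (two-sided t-test, α = 0.05 default) and declares
the shapes indistinguishable when the maximum pairwise adjusted-R²
difference is below 0.02. The 0.02 threshold is this package's
operationalization of "similar explanatory power" — configurable and
always reported in the output. `split_fit` repeats the comparison on the
two sides of a split position (default x = 310 µm, matching the
anterior/posterior split used for the imaged 230–330 µm window).

## Noise statistics

**Spatial noise.** Each row of cells is fit with its own best gradient
model (highest adjusted R² among linear/exponential/quadratic, or a fixed
model on request); the statistic is the maximum over rows of the residual
range (max − min), divided by the amplitude (max − min) of the *pooled*
best-fit curve over the rows' common position range, × 100. Residual
range was chosen over a standard-deviation measure because "variability
as high as X% of the gradient" is a statement about extreme cell-to-cell
excursions; the fitted-curve amplitude (not the raw data range) defines
the gradient magnitude so single outliers cannot inflate the denominator.
The statistic is invariant to adding a constant to all abundances, to row
relabeling, and to joint rescaling of the values.

**Temporal CV.** Sample standard deviation (ddof 1) over mean; two points
suffice. The deviation series (value − mean) is retained for plotting.

**Moving-window autocorrelation.** Defaults: window 30 points, step 1,
max lag 20, linear detrend per window, α = 0.05 — all configurable and
recorded in the result. Per window the sample autocorrelation is computed
per lag; the across-window mean correlation is tested against zero with a
t-test whose sample size is the number of *non-overlapping* windows
(n_windows·step/window), because overlapping windows are heavily
dependent and the naive count would be wildly anticonservative. A seeded
permutation test (shuffling the trace) is available as an alternative.

Significant lags are restricted to the first *recurrent* positive lobe of
the mean autocorrelation: the positive run contiguous with lag 0 reflects
smoothness of the process, not periodicity, while a genuine oscillation
reappears as a detached positive lobe near its period. Without this rule
a sinusoid flags lags 1–2 as strongly as its period and the mean
significant lag is meaningless. With it, a 162-s sinusoid sampled at 12 s
flags the cluster around lags 13–14 (13.5 = 162/12), and the dominant
period — mean significant lag × Δt — recovers 162 s; the estimator's
type-I rate on white noise is well below the nominal α because the
short-window autocorrelation bias is negative.

**Group comparisons.** Levene's test uses the mean-centered variant
(center="mean"); per-cell CVs across groups are compared by one-way
ANOVA. Mean-centered expression subtracts each cell's embryo×region mean,
removing embryo-level heterogeneity before comparing cell-to-cell
variance across conditions; singleton embryo-region groups are excluded
with a log entry.

## Stochastic RA-network model

Per cell i on a 1-D chain (anterior at index 0, source in the posterior
20%), the state is extracellular RA R_ext, free intracellular RA R_free,
RA–binding-protein complex C, degrading enzyme Y, and toggle genes K
(krox20-like) and H (hoxb1a-like):

    dR_ext = D·ΔR_ext/h² + β·1(source) − k_in R_ext + k_out R_free
    dR_free = k_in R_ext − k_out R_free − k_on R_free(B_tot − C) + k_off C
              − k_cyp Y R_free
    dC     = k_on R_free(B_tot − C) − k_off C − δ_C C
    dY     = α₀ + α_Y C^n/(K_Y^n + C^n) − δ_Y Y
    dH     = β_H (basal + (C/K_ra)^p + (H/K_selfH)^m) /
             (1 + basal + (C/K_ra)^p + (H/K_selfH)^m + (K/K_cross)^m) − δ_H H
    dK     = β_K (basal + (K/K_self)^m) /
             (1 + basal + (K/K_self)^m + (H/K_cross)^m) − δ_K K

The complex C is the signaling species (the binding protein delivers RA
to its receptor), so C induces Y and activates H. Every unidirectional
reaction channel a contributes √(a/ω)·dW (chemical Langevin); transfer
channels (diffusion hops, uptake/efflux, binding/unbinding) share one
Wiener increment between source and destination state, so transport noise
conserves mass pathwise. Non-negativity is enforced by reflection.
Boundary conditions are zero-flux; ω → ∞ recovers the deterministic
limit. The toggle's channels use an effective system size
ω·gene_size_ratio (default 0.05): gene products are present at far lower
copy number than the RA pools, and without this the toggle would be
frozen on simulation timescales. Scaling ω still scales *all* noise, so ω
remains the single noise dial.

**Fixed and calibrated parameters.** k_off = ln 2 / 1.7 ≈ 0.408 min⁻¹ is
fixed by the 1.7-min complex half-life. The rest are calibrated, in this
order of intent:

- Geometry: 80 cells × 5 µm (400 µm domain covering the imaged window),
  D = 100 µm²/min, posterior 20% source. Net uptake
  k_in(1 − k_out/(k_out + k_cyp Y*)) ≈ 0.0106 min⁻¹ gives a ~100-µm decay
  length, so free RA declines anteriorly across the whole domain.
- k_in = 0.017, k_out = 0.15, k_cyp·Y* = 0.25 min⁻¹ (Y* ≈ 0.05 with
  α₀ = 0.002, α_Y = 0.008, δ_Y = 0.2); β = 20 sets the copy-number scale
  of RA high so that intrinsic (Poisson-like) noise in R_free is small.
- The dominant noise source is, by design, the slow fluctuation of the
  low-copy enzyme Y (CV_Y = 1/√(Y*ω), correlation time 1/δ_Y = 5 min),
  transmitted to R_free through the degradation rate. This structure is
  what produces the observed dissociation: the buffer (B_tot = 70,
  K_d = k_off/k_on ≈ 20 comparable to mid-domain R_free) slows the
  effective response of the free pool by the factor 1 + θ with
  θ = B_tot·K_d/(K_d + R)², filtering the 5-min enzyme noise — so B_tot
  reorders the CV while binding fluxes cancel at steady state and leave
  the mean untouched. Scaling the enzyme expression (α₀, α_Y ×0.2 / ×5)
  shifts the mean strongly (locally and through the gradient length)
  while its two effects on the CV — more intrinsic noise at lower mean,
  less transmitted noise from a higher-copy enzyme — largely offset.
- ω = 300 places the 5-row spatial-noise statistic at a median ≈ 57%
  (all probed seeds ≥ 45%) and a mid-domain temporal CV near 0.06–0.10.
- Toggle: β = 0.5, δ = 0.1 min⁻¹ (on-level 5), m = 2, p = 4,
  K_self = 2, K_self_H = 3.5, K_cross = 1.5, K_ra = 25 (the mid-domain
  complex level), basal = 0.2. The weaker H self-activation plus the leak
  bound the bistable band on both sides (C ≈ 15–27), so misassigned cells
  outside the band relax deterministically and cells inside it must be
  corrected by noise-induced switching.

Perturbation presets scale B_tot (crabp2a) or α₀ and α_Y (cyp26a1) by
0.2 (morpholino) or 5.0 (gain of function); knockdown efficiencies are
not known, so the factors are configurable presets.

**Initialization and integration.** Runs start from the deterministic
steady state, obtained by Picard iteration (pointwise intracellular
equilibrium nested inside a tridiagonal solve of the extracellular
balance) — integrating from zero would need several hundred minutes
because the slowest spatial mode relaxes at ~0.01 min⁻¹. A stochastic
burn-in (default 50 min) then equilibrates the fluctuations before
recording every 12 s (the experimental cadence). Euler–Maruyama with
dt = 0.005 min; a precondition rejects dt·(max per-capita rate) ≥ 0.1 and
the integrator raises if a state goes non-finite. Identical
(params, seed) give bitwise-identical trajectories; ensembles integrate
all realizations as one batch driven by a single master generator and are
reproducible from (params, master seed, n_real).

**Boundary metrics.** A cell is K-positive above half the K-on level.
The final boundary is set by the K-positive count at the last recorded
time; misexpression counts cells on the wrong side of it, the mixed zone
spans from the first K-negative to the last K-positive cell, and the 1-D
sharpness score is 1/width (1 when the zone is empty). The "noisy" gene
initialization seeds the toggle from a jittered threshold on C plus a
sparse fraction of outright flips, at raw on/off levels — an initially
rough pattern whose subsequent cleanup (or failure to clean up at 100×
noise) is the object of study.

## Expression quantification and sharpness

Per-cell totals are raw 3-D sums over each label's voxels (no projection
or contrast adjustment); centroids and voxel counts are returned, empty
labels are skipped with a log entry. Boundary tracing walks the lateral
(y) axis and takes, per row, the anterior-most or posterior-most member
pixel of the single connected region; the polyline through these pixel
centers has steps of 1 px (straight) and √(1 + Δx²) px (shifts).
In the fine-pixel limit a coarse staircase of equal lateral and axial
extent approaches √2 × its endpoint distance, and a 45° sawtooth boundary
gives S → 1/√2; both limits are oracle-tested. S = Σd_sharp/Σd_xy is
independent of slice thickness (it cancels algebraically; asserted at
runtime) and of pixel size. Stripe masks can be derived from per-cell
totals by Otsu thresholding of per-cell mean intensities followed by
largest-connected-component selection, but manually drawn masks are
always accepted — expert segmentation overrides the automatic split.

## Synthetic data: what it emulates, what it does not

- FLIM cubes: Poisson photon statistics over wrapped-exponential mixture
  decays of configurable lifetimes (defaults RA 0.35 ns, background
  2.5 ns — plausible two-photon values, not measurements). No optics PSF,
  detector afterpulsing, or spectral bleed-through.
- Gradient rows: shared linear/exponential base curve over 230–330 µm
  plus i.i.d. Gaussian per-cell deviations whose scale is calibrated by a
  seeded Monte-Carlo (including the per-row detrend) so the *expected*
  spatial-noise statistic equals the requested percentage. Real rows have
  spatially correlated deviations; the generator's are independent.
- Temporal traces: Ornstein–Uhlenbeck noise (correlation time 6 s, i.e.
  sub-sampling-interval) plus an optional sinusoid; snr is the RMS
  signal-to-noise ratio. A clean sinusoid is a stand-in for whatever
  oscillatory process underlies the real fluctuations.
- Expression stacks: jittered-grid (Poisson-disc-like) tiling at ~85 px
  mean in-plane cell size across the whole field; two stripes whose edges
  wander by a smoothed random walk of standard deviation `roughness` px;
  expressing cells draw lognormal totals (default mean 190,000, safely
  under 12-bit clipping at ~2235 per pixel), non-expressing cells get 2%
  residual signal. Cells are z-columns; real cells are rounded and real
  boundaries are cell-granular rather than pixel-granular.

Passing tests on these generators demonstrate estimator correctness and
calibration under the stated statistical assumptions — not performance on
real embryos, where segmentation error, optical artifacts, and correlated
biological variability are all present.

## Problem sizes used by the shipped checks

The test suite and the reproduction script run, by choice, at the scale
that makes each claim statistically meaningful while staying lightweight:
20 master seeds × 5 rows × (50 + 100) min for the spatial-noise statistic;
20-realization averages over a 60-min window at a fixed cell (index 48,
where the buffer operates near K_d) for the five-condition dissociation;
6–20 seeds for boundary-sharpening comparisons; 1000 white-noise traces
for the autocorrelation type-I check.

## Known limitations

- The Langevin approximation is the contract: no Gillespie exactness, no
  2-D/3-D tissue geometry, cell movement, or division.
- Quantitative trajectories are calibration-dependent; only the
  documented qualitative orderings (CV vs mean dissociation, noise-level
  effects on sharpening) are asserted, and they are asserted under the
  default calibration only.
- The downstream "both-directions" increase of expression variance under
  either perturbation is parameter-dependent in this model class and is
  treated as a calibration goal for the synthetic condition bundles, not
  a guaranteed model invariant.
- The exponential gradient fit is least-squares optimal on the log scale,
  not the data scale; for the shallow gradients in scope the difference
  is negligible, which is itself the scientific point.
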