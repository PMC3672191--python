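# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## FCS forward model

The observation volume is a 3D Gaussian; for a mixture of up to two freely
diffusing species the normalized fluorescence autocorrelation is

    G(τ) = B + (1/N) Σᵢ fᵢ (1 + τ/τ_D,i)⁻¹ (1 + τ/(s² τ_D,i))^(−1/2)

* `N` — occupancy, the mean molecule number in the volume. Related to molar
  concentration through the effective volume V_eff = π^{3/2} ω₀² z₀ (a
  reporting convention: only concentrations depend on it, never fitted D).
* `fᵢ` — amplitude fractions summing to one, under the equal-brightness
  assumption; no brightness correction is applied.
* `τ_D = ω₀²/(8D)` for two-photon excitation — squaring the illumination
  profile shrinks the detection volume and halves the residence time —
  or `ω₀²/(4D)` for one-photon; the mode is a field of `BeamGeometry`.
* `B` — additive baseline, fixed at 0 by default. No triplet/photophysics
  term is modelled (out of scope, as is detector afterpulsing and FCCS).

Units are fixed package-wide: lags in s, D in µm²/s, beam radii in µm,
hydrodynamic lengths in Å, T in K, η in cP, trajectory coordinates in nm
and frame times in ps. Defaults T = 298.15 K, η = 0.89 cP (water, 25 °C).

Beam calibration follows the conventional dye-reference procedure:
ω₀ = sqrt(k·D_ref·τ_D,ref) with rhodamine 110 (D_ref = 300 µm²/s) as the
default standard.

## Fitting and model selection

Weighted least squares (residuals (g−model)/σ, σ = 1 when absent) via
bounded trust-region minimization (lmfit), multi-started over log-spaced
diffusion-coefficient initializations because the two-species objective is
multimodal. The two-species fit always includes a start seeded at the
nested one-species optimum, which guarantees χ²(2sp) ≤ χ²(1sp) numerically.
Default bounds: D ∈ [0.1, 1000] µm²/s, N ∈ (0, 10⁴], fractions ∈ [0, 1].
Species are reported sorted by descending D, so D1/F1 always denote the
faster species. Selection between nested fits is parsimonious: two species
only when reduced χ² improves by more than 10% (relative) **and** the minor
fraction exceeds 0.5%; both thresholds are arguments.

Identifiability is the binding constraint for minority species: at 2%
per-point multiplicative noise, a ~3% slow component is only resolved on a
dense lag grid. The recovery studies therefore use 1024 log-spaced lags
over 1 µs–1 s — the density a software correlator yields from a photon
stream — where the maximum-likelihood estimate is unbiased (the replicate
study in the acceptance script measures this); on sparse 64–96-point grids
a genuine degenerate optimum (intermediate fraction, compressed D values)
biases the mean fitted fraction low. This is a property of the estimation
problem, not of the optimizer.

Uncertainty: residual-resampling bootstrap, refitting each resample from
the original optimum, reporting 16/84-percentile intervals (nominal 68%
coverage), deterministic under a fixed seed.

## Hydrodynamic interpretation

Stokes–Einstein R = kT/(6πηD); Wilkins native scaling R_N = 4.75·N^0.29 Å
(published central coefficients, configurable; no uncertainty propagation);
Perrin prolate friction factor relative to the equal-volume sphere,

    F(p) = √(1−p²)/(p^{2/3} ln[(1+√(1−p²))/p]),  F(1) = 1,

with D_ellipsoid = D_sphere(R_eq)/F(p), R_eq = (a b²)^{1/3}. `invert_prolate`
solves F(p) = D_sphere/D_meas by Brent bracketing on p ∈ [10⁻⁴, 1] to
machine tolerance and verifies the round trip to 1e-10 relative; a measured
D above the sphere bound raises `NoProlateSolutionError`, one requiring
p < 10⁻⁴ raises `OutOfModelError`. Note that under a fixed ~10⁵ ų volume
a two-fold slowdown demands an extreme axial ratio (p ≈ 0.05, a ≈ 200 Å):
the equal-volume prolate model attributes *all* of the slowdown to shape,
whereas real measurements at such pH values also contain heterogeneity and
aggregation; the model is a bounding interpretation, not a structure
determination. Oblate spheroids, rotational diffusion and hydration-shell
corrections are out of scope.

## Synthetic data

`simulate_curve` multiplies the analytic curve by (1 + cv·ζ), ζ ~ N(0,1)
i.i.d., and stores σ = cv·G_true — a deliberately simple noise model
adequate for exercising the fitter; full correlator noise theory (lag
correlations, photon statistics) is not emulated, so passing fitting tests
says nothing about detector artifacts in real data.

`simulate_photon_trace` is the physical ground truth: point emitters take
Gaussian steps of per-axis variance 2·D·dt in a periodic box centered on
the focus, the expected count per bin is Σ β·dt·exp(−4r²/ω₀² − 4z²/z₀²)
(squared-Gaussian two-photon profile), and counts are Poisson draws.
Enforced preconditions: dt ≤ τ_D/20 of the fastest species, every box side
≥ 10 ω₀. The box may be anisotropic: a cubic box a few times z₀ under-
resolves the slow axial decay with its discrete diffusion modes and biases
fitted D high by several percent, so the validation studies use
(4, 4, 12) µm with z side 6 z₀, where the residual bias is ~2%. Because the
box is closed, G(∞) → −1/N_box; fits of simulated traces therefore free the
baseline. Steps are generated in float32 (ample for µm-scale paths, ~2×
faster). Photobleaching, blinking, dead time and flow are not modelled.

`multitau_correlate` evaluates lags 1..m (default m = 16) at native
resolution, then repeatedly halves the resolution (summing adjacent bins)
and evaluates lags m/2+1..m, giving a quasi-logarithmic grid reaching at
least a quarter of the trace duration. Normalization is symmetric (separate
left/right segment means), removing the leading finite-length bias. With
`n_segments > 1` per-point standard errors come from the scatter of
segment-wise correlations; these σ estimates from ~10 segments are noisy,
so the pipeline studies fit the full-trace curve unweighted rather than
risk over-weighting accidentally small σ.

`titration_scenario` encodes a pH-unfolding profile: the fast-species D
interpolates (pH, D) knots (2, 25), (4.5, 50), (6, 50), (7, 84), (10, 31),
(11, 31) µm²/s, and a slow aggregate species (D = 15 µm²/s) has fraction
0.002 + 0.098·clip(|pH−7|/4.5, 0, 1)³ — ≈0.2% at neutral pH (negligible,
below the selection floor), ~3% at pH 4/10, ~10% at the extremes. Occupancy
derives from a 10 nM sample concentration and the beam's effective volume.
Per-pH seeds are spawned from one root seed, so the dataset is a pure
function of (parameters, seed).

`toy_trajectory` plants known structure: `static` (identical frames),
`diffusive` (rigid body, center-of-mass Brownian motion of known D), and
`two-state` (two reference conformations separated by a set RMSD, exact
state counts, Gaussian jitter). These fixtures have no bonded structure,
solvent, or periodic imaging — trajectory tests validate the statistics,
not MD physics.

## Trajectory statistics

* **MSD** — averaged over selected atoms and all time origins (sliding
  window, FFT-based), which reduces variance relative to the
  first-frame-only definition; requires uniform frame spacing. Because
  all-origin MSD noise grows with lag, diffusion fits use an early-lag
  window (the validation studies fit lags up to 0.2% of the trajectory
  length); `einstein_diffusion` exposes the window as fractions of the
  maximum lag and reports D = slope/6 with the OLS standard error (which
  ignores lag-lag correlation and is therefore optimistic).
* **RMSD** — least-squares (Kabsch) superposition by default, via rotation
  alignment; mass-weighting is off (a `masses` argument exists for Rg).
  The all-pairs matrix uses the closed-form Kabsch result with batched 3×3
  SVDs, with the proper-rotation determinant correction.
* **Daura clustering** — greedy neighbor counting on the superposed-RMSD
  matrix at a cutoff (default 0.25 nm); ties in neighbor count break to the
  lowest frame index (the original algorithm leaves this open). Cluster
  centers are member frames by construction.
* **PCA** — frames iteratively superposed to their mean (3 iterations),
  covariance of the flattened Cα coordinates (1/n normalization),
  `eigh` decomposition, eigenvalues clipped at 0 and sorted descending.
  All-Cα selection makes mass weighting a constant factor.
* **FEL** — 2D histogram of two projections, ΔG = −ln(P/P_max) in kT, the
  occupied minimum exactly 0; unvisited bins are NaN and flagged, never
  assigned an arbitrary cap. Bin count is a parameter (default 32); note
  the gap between two *states* equals the gap between two *bins* only when
  each state's cloud occupies a single bin.

## Pipeline

`run_titration` fits both models per pH, selects, converts the fast D to a
Stokes–Einstein radius, and attempts the equal-volume prolate inversion.
The reference volume defaults to the sphere volume of the largest selected
D in the run — anchoring the constraint to the most compact (native) state
— and is overridable. Failures are isolated per pH (recorded in the row's
`error` field). Reports (CSV + JSON with config hash, seeds, version) are
byte-deterministic for fixed config and input.

## Problem sizes used in validation

The recovery studies are sized to give adequate statistical power while
staying desk-runnable: 200 replicate curves for the two-species study;
ten 15-s photon traces of 150 emitters at 3×10⁵ cps (1.5×10⁶ bins each)
for the pipeline study; twenty 10⁴-frame single-particle trajectories for the
Einstein-relation study; ≤1000-frame trajectories for clustering/PCA.

## Known limitations

* Equal-brightness amplitude fractions; no brightness correction.
* No triplet kinetics, afterpulsing, bleaching, or flow terms.
* The Brownian simulator's periodic box leaves a ~2% high bias in
  pipeline-recovered D at the validation geometry (axial mode resolution);
  enlarging the z side reduces it at linear cost in emitters.
* Bootstrap intervals and OLS slope errors understate uncertainty when
  residuals are correlated.
* PDB trajectory I/O does not carry frame times (format limitation); XYZ
  (with times on the comment line) is the lossless interchange format.
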