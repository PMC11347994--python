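# Methods

This note documents the models implemented in `serspen`, their default
parameters, the numerical choices behind them, and what the synthetic
scenes do and do not emulate.

## Data model

A `HyperMap` is one time-stamped cube: an `n_depth × n_lateral` grid of
spectra on a shared, strictly increasing wavenumber axis (cm⁻¹). Depth
index 0 is the pericarp surface and increases inward; the default grid is
40 × 20 pixels at 5 µm spacing (≈200 µm depth window) with 256 channels
over 400–1800 cm⁻¹. Cubes round-trip through HDF5 (bit-exact) or a
tab-delimited matrix with a JSON sidecar (≤1e−9 relative).

## Preprocessing

Fluorescence from fruit pulp dominates raw SERS spectra. Baselines are
estimated by asymmetric least squares: a Whittaker smoother with
second-difference penalty (smoothness λ = 1e5) and asymmetry weights
(p = 0.01, 10 reweighting iterations). These are the standard Raman
defaults; λ controls baseline stiffness (larger = smoother), p the
fraction of the residual allowed above the baseline. Corrected spectra may
dip below zero; negatives are retained through the similarity stages (they
carry no bias for correlation metrics) and clipped to zero only where the
non-negative factorization requires it.

## Unmixing (VCA)

Vertex component analysis assumes the linear mixing model with at least
one (nearly) pure pixel per component. The signal subspace is chosen by an
SNR estimate: energy in the top-p singular directions versus the residual,
corrected for the noise share inside the subspace. Above the canonical
threshold `15 + 10·log10(p)` dB the data are reduced by an uncentered
rank-p SVD with projective scaling; below it by mean-centered rank-(p−1)
PCA lifted with a constant coordinate. Endmember search then iterates
orthogonal random probes (seeded generator; ties resolve to the lowest
pixel index; a pixel is never picked twice). Returned endmembers are the
selected pixels' reconstructions in the signal subspace — identical to the
raw pixels for exact low-rank data, denoised otherwise.

The endmember count `p` defaults to the number of expected pesticides plus
one (fluorescence/background). Matching to library references minimizes
the total spectral angle under a one-to-one assignment
(`scipy.optimize.linear_sum_assignment`); assignments worse than
`max_angle` (default 0.2 rad) fall back to the `background` label. With
two co-penetrating pesticides in one cube no pixel is pure and matching
needs a looser angle; single-pesticide cubes — the arrangement the imaging
experiments actually use — match comfortably inside the default.

## MCR-ALS

Alternating exact NNLS solves: per-pixel for `C` given `S`, per-channel
for `S` given `C`. Both sub-solves are exact, so the lack of fit is
non-increasing; the scale ambiguity is fixed by rescaling each `S` row to
unit maximum with the factor absorbed into `C` (reconstruction invariant).
Only non-negativity is imposed — no unimodality or closure, because depth
profiles are legitimately non-monotone here. Defaults: relative-LOF
tolerance 1e−6, 200 iterations max, initialization from matched VCA
endmembers; an LOF below 1e−9 % counts as exact convergence.

## Similarity and label maps

Pixels are baseline-corrected and l2-normalized before comparison. The
headline decision rule uses Pearson correlation against the reference
(bounded, scale-free): strictly above 0.8 ⇒ `pesticide`; 0.5–0.8
inclusive ⇒ `suspected` (partially metabolised signal); below 0.5 ⇒
`background`. Mixture overlap maps use Euclidean-distance similarity
`1/(1+d)` on normalized spectra against each reference independently and
encode presence additively (defaults 0/10/20/30). Note the geometry: on
normalized spectra `1/(1+d) > 0.8` requires the pixel to be within ~14° of
the reference, so a 50/50 mixture of orthogonal fingerprints cannot exceed
the default cutoff against either component — overlap studies typically
lower the ED cutoff (it is a config field), while the 0.8/0.5 semantics of
the categorical rule are fixed.

## Profiling

Content (an MCR abundance column, or a characteristic-peak maximum within
±10 cm⁻¹ when unmixing is skipped) is averaged over all lateral pixels per
depth bin (default bin = one grid row; bins tile [0, extent], last bin
closed). The total-content curve averages each profile over bins (a
pixel-weighted mode exists for unequal bins) and is smoothed by a cubic
regression B-spline with df = 6 basis functions for the 10-point time
course — flexible enough to express the weakening dip, stiff enough not to
chase noise; `df = n` interpolates.

## Spatial machine learning

Curation mirrors how an unlabeled imaging corpus becomes a training set:
over-cluster with K-means (k defaults to twice the number of expected
classes; best of 10 k-means++/Lloyd restarts), compare each centroid to the
labeled VCA endmembers by Pearson correlation, and keep only confident
clusters — above the pesticide threshold the cluster inherits that label,
below the suspected threshold it becomes background, the ambiguous band is
discarded rather than trained on. A practical consequence: when weak-dose
pesticide spectra and background land in one cluster, its centroid sits in
the ambiguous band and the whole cluster is dropped, which can remove the
background class entirely; classification then separates the pesticide
classes from each other, matching the two-pesticide evaluation design.

Splits are stratified per class with train count = round-half-up of
0.7·n. Classifier families — LDA, standardized logistic regression,
standardized linear SVM, random forest (100 trees) — are wrapped
one-vs-rest so each exposes per-class continuous scores. ROC curves come
from an exact threshold sweep with tied scores collapsed into single
steps, so the trapezoidal AUC equals the pairwise statistic
P(s⁺ > s⁻) + ½·P(tie) exactly.

## Synthetic scenes

A cube pixel is `gain(z,x) · [Σ_k c_k(z,t)·S_k(ν) + baseline(ν)] + ε`:

- **Fingerprints**: sums of Lorentzian bands (FWHM 14 cm⁻¹; Gaussian
  available), band positions loosely modeled on published SERS bands of
  chlorpyrifos and acetamiprid.
- **Baseline**: a broad Gaussian bump (amplitude 300 a.u., center
  1100 cm⁻¹, width 600 cm⁻¹) plus a gentle slope — the fluorescence
  background shape.
- **Gain field**: lognormal with log-std 0.15, spatially correlated over
  10 µm, unit mean — the multiplicative image bias of a heterogeneous
  enhancing substrate.
- **Noise**: additive Gaussian, default σ = 20 a.u.;
  `benchmark.noise_sd_for_snr` derives σ for a target cube SNR.
- **Penetration**: `∂c/∂t = D·∂²c/∂z² − k0·A(t)·R(t)·c` on the depth
  window, surface boundary `c(0,t) = dose·exp(−t/τ_surf)` (spray drying
  off), zero flux at the inner boundary. The enzymatic defense is
  *induced*: activation `A(t) = 1 − exp(−t/t_act)` ramps up after
  exposure, while the reserve obeys
  `dR/dt = −γ·A·R·⟨c⟩_z + s·(E0 − R)`, `R(0) = E0`. Setting `t_act = 0`
  recovers an always-active defense — under which, provably, the front
  depth is monotone (the solution approaches its steady profile from
  below, and any early enzyme rise is precluded because consumption is
  proportional to the mean concentration, which peaks during the initial
  free-diffusion phase). The induction lag is the minimal addition that
  produces the three observed phases: diffusive advance while the defense
  is latent, retreat while the activated enzymes degrade the invader, and
  renewed advance once the reserve is consumed.

  Defaults for the non-systemic component: D = 50 µm²/h, k0 = 2/h,
  E0 = 1, γ = 3, s = 0.02/h, t_act = 12 h, dose = 1.5, τ_surf = 96 h —
  chosen once so the front trajectory over the 2–96 h schedule shows the
  three phases with clear margins (26 → 30 → 26 → 58 µm). The systemic
  component penetrates deeper with weaker degradation (D = 80 µm²/h,
  k0 = 0.5/h, persistent surface supply). The solver is explicit in the
  diffusion term (stability `D·Δt/Δz² ≤ 0.4`, internal sub-stepping) with
  exact exponential updates for the degradation and enzyme terms
  (mid-step activation), on a 1 µm depth grid; trapezoid mass is exactly
  conserved in the source-free, degradation-free limit.
- **Labeled spectra**: per pesticide class `dose·S_k + baseline + ε` with
  dose log-uniform in [0.1, 2.0]; background is baseline + noise.
  One seeded generator per scene; per-time-point noise streams are derived
  by fixed offsets so any cube is independently reproducible.

What the generator does **not** emulate: cosmic-ray spikes, wavenumber
calibration drift, nonlinear enhancement saturation, spatially varying
baselines, 3-D (x,y,z) geometry, and pesticide–pesticide chemical
interaction. Passing recovery tests therefore demonstrate correctness of
the algorithms under the stated generative assumptions, not instrument
robustness on real spectra.

## Problem sizes and benchmarks

The recovery and classification benchmarks use desk-scale problems chosen
to exercise every stage: 32×32-pixel cubes for unmixing oracles,
single-pesticide 32×16 cubes at 25 dB for MCR recovery, and 5000 spectra
per class (two pesticides + background) for the curated classification
benchmark, whose held-out one-vs-rest AUC is the quantity
`scripts/acceptance.py` reports. The demo pipeline configuration runs a
30×12 grid over all ten acquisition times.

## Known limitations

- Per-pixel NNLS loops in Python; cubes beyond ~10⁴ pixels per time point
  are slow (minutes, not seconds).
- VCA assumes pure pixels; in co-penetration mixtures the extracted
  endmembers are the extreme mixtures, and matching/labeling then depends
  on a looser angle threshold.
- The penetration model is phenomenological — its parameters are effective
  rates for reproducing dynamics, not measured enzyme kinetics.
- No absolute concentration calibration: all contents are relative (a.u.).
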