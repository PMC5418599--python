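# Methods

This note records the models, numerical choices and known limitations of
`pointloc`, in the spirit of a methods supplement.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## EMCCD count model (`pointloc.emccd`)

The offset-subtracted count `c` of a pixel with expected photon number `E`
has density

    p(c|E) = e^{-E} N(c; 0, r²) + ∫₀^∞ f(u; E, g) N(c−u; 0, r²) du,
    f(u; E, g) = sqrt(E/(u g)) e^{-u/g − E} I₁(2 sqrt(E u/g)),

the high-gain limit of the EM-register cascade (gain `g`, readout s.d. `r`).
The convolution with the readout Gaussian is evaluated by fixed Gauss–Hermite
quadrature of order 33; the zero-photon atom is handled analytically as
`e^{-E} N(c; 0, r²)`, which keeps the density proper (quadrature
normalization error is below 10⁻⁶ for `E` up to 50, checked in the tests).
Counts are treated as continuous reals: the readout noise already smooths the
ADU grid.  The sampler draws the same cascade (Poisson → Gamma → Gaussian),
so simulation and likelihood are two faces of one model.  ADC clipping and
sCMOS-style per-pixel noise maps are not modelled.

Default camera: gain 50, offset 100 counts, readout s.d. 10 counts, 80 nm
pixels.

## Spot model (`pointloc.spotmodel`)

Pixel intensities are `E_i = b + N ∫_pixel g(x,y) dA` with a unit bivariate
Gaussian `g`; the asymmetric variant uses covariance
`R(φ) diag(σ₁², σ₂²) R(φ)ᵀ` (φ modulo π).  Pixel integrals use
tensor-product Gauss–Legendre quadrature, order 5 per axis; against the
closed-form erf product for axis-aligned spots this is accurate to better
than 10⁻⁶ relative for widths down to half a pixel, the narrowest regime the
priors allow.  The focused-spot width is `σ₀ = 0.21 λ/NA` (95.85 nm at
639 nm / NA 1.4, the default optics).

## Localization (`pointloc.localize`)

Internal optimizer coordinates: position in pixels; `ln b`, `ln N`; width as
`ln σ` (MLE) or `ln Δσ` (MAP) with `σ = σ₀(1+Δσ)` — so MAP widths are
structurally above the diffraction limit.  Priors: exponential on Δσ (mean 1
symmetric; 1/2 per principal width asymmetric), normal on `ln b` (s.d.
ln 30), flat elsewhere.  The background prior is a density in `ln b`
directly; the width prior is a density in Δσ and the `ln Δσ` change of
variables contributes its Jacobian to the objective — the reported optimum
therefore maximizes the posterior density in (Δσ, ln b).

Optimization is BFGS with 2-point finite-difference gradients (relative step
10⁻⁶, gradient tolerance 3·10⁻⁴); "precision-loss" terminations with a
gradient norm below 0.05 are accepted as converged, since with
finite-difference gradients the noise floor sits well above the nominal
tolerance.  Seeds: ROI centre (or the supplied position), `b` from the ROI
border median, `N` from the background-subtracted ROI sum, `Δσ = 0.5`.

The Laplace precision is the position s.d. from the full inverse Hessian
(central differences, step 10⁻⁴ in internal coordinates); fits with a
non-positive-definite Hessian are flagged and report no precision.  The CRLB
uses the Rieger–Stallinga approximation with `σ_a² = σ² + a²/12`,
`τ = 2π σ_a² b/(N a²)` and an overall factor 2 for EMCCD excess noise.

Retention filters (applied against the seed): converged; within 4 px
(Euclidean); estimated uncertainty < 16 px; width < 9 px.  Conditional
consistency uses 7.5 nm precision bins with at least 300 spots per bin.

## Synthetic movies (`pointloc.simulate`)

The generator emulates tracking in a rod-shaped bacterium: Brownian motion
(Euler–Maruyama, ≥10 substeps per frame) in a cylinder (default 20 μm ×
0.8 μm, specular reflection at wall and caps), optional multi-state dynamics
(Markov rates or a scripted event list with binding-site z anchors),
continuous or shorter exposure, Poisson photon emission apportioned over the
illuminated substeps, a constant or exponentially decaying uniform
background, and the EMCCD cascade per pixel.  Defocus uses a Gaussian-beam
law `σ(z) = σ₀ sqrt(1 + (z·s/z_R)²)` with depth scale `z_R` (default
400 nm) and a z-rescaling factor `s`; it is a deliberately simple stand-in
for a full vectorial PSF — it broadens the spot but has no rings, asymmetry
or polarization structure.

The motion-blur strength is gauged by the time-averaged spread of the
in-plane path about its exposure mean, `sqrt(D t_E/3)` per axis, divided by
σ₀ (the prefactor 1/3 is verified against a brute-force path simulation in
the tests); a ratio below 0.5 is "weak blur", crossing near t_E ≈ 7 ms for
D = 1 μm²/s with the default optics.

`fig6_scenario` scripts a two-state binding/unbinding experiment: free
diffusion at 1 μm²/s alternating with four bound (0.1 μm²/s) intervals of
different durations, two of them at membrane sites ~400 nm out of focus;
200 Hz, continuous illumination, 300 photons/spot on average, background
decaying 0.95 → 0.75 photons/pixel with a 0.75 s time constant.  For this
scenario the defocus depth scale is set to 100 nm: the Gaussian-beam law
with the 400 nm default underestimates how severely a high-NA vectorial PSF
degrades localization several hundred nm out of focus, and the shorter scale
restores the several-fold precision loss at the defocused binding sites that
such experiments show.

For large HMM ensembles, `track_observations` bypasses rendering: observed
positions are the true exposure averages plus Gaussian noise whose s.d. is
the CRLB at each frame's conditions — defocused width, motion-blur-widened
width (`D t_E/3` in quadrature), per-frame Poisson photon count, current
background.  This reduced-fidelity route keeps the error *pattern*
(state- and depth-dependent, fluctuating) while making 200-replicate
ensembles run in minutes.  What it does not capture: non-Gaussian error
tails, fit failures, errors exceeding the CRLB for strongly defocused
non-Gaussian spots, and correlations between localization error and the
within-frame path.  Conclusions drawn from it about *relative* method
performance are therefore conservative: real error variability is larger.

## Diffusion estimators (`pointloc.diffusion`)

`d_cov` combines both step moments, cancelling blur and noise without
external input; `d_cov_eps` uses the mean localization-error variance (from
the Laplace precisions) and the blur coefficient.  Negative estimates are
kept (flagged downstream) so ensemble means stay unbiased.  Per-axis moments
are pooled by averaging.  The likelihood-based single-state estimator is the
K = 1 case of the HMM, where the variational factorization is exact.

Correction of simplified-model fits (step-variance matching):
`D* = D/(1−2R)` for the Kalman limit and `D* = (D − ε̄²/Δt)/(1−2R)` for the
vbSPT-like limit.  With strongly variable errors the subtraction should use
the per-state (posterior-occupancy-weighted) mean error variance: a global
average can overshoot for a state whose frames happen to carry small errors
— in the binding scenario it drives the slow state's corrected D negative.

## Diffusive HMM (`pointloc.hmm`)

Observation model per axis: `x_t = (1−τ) y_t + τ y_{t+1} + η_t` with
`Var η_t = ε_t² + 2 D_{s_t} Δt β`, path steps `Var(y_{t+1}−y_t) = 2 D_{s_t}
Δt`, states Markov.  `τ` is the shutter's first moment and
`β = τ(1−τ) − R`; this two-point embedding reproduces the blurred-camera
step covariances exactly, for any shutter.  Shutter handling is numeric
(point masses, `R = ∫S(1−S)`), with the continuous shutter's (1/6, 1/2,
1/12) in closed form.

Inference: variational EM with `q(s)·q(y)`.  `q(y)` is a banded-precision
Gaussian chain solved by an LDLᵀ factorization with Takahashi recursions for
the in-band covariance entries (O(T) per sweep, JIT-compiled); `q(s)` is
scaled forward–backward.  The ELBO is `ln Z_s + H[q(y_x)] + H[q(y_y)]`
(flat prior on the initial position) and is asserted non-decreasing at every
iteration; for K = 1 the factorization is exact and the converged ELBO
equals the marginal log-likelihood of the steps (tested against a direct
MA(1)-covariance evaluation).  M-steps for π and A are closed form; for D_k
the observation variance couples D non-conjugately when β > 0, so the
package uses an exact bounded 1-D search per state with a monotonicity guard
(generalized EM).  Axes share states and D but have independent paths;
states are sorted by ascending D after fitting; state labels in
misclassification comparisons use the same convention.

Initialization: D values log-spaced over [0.2×, 2×] a blur- and
noise-corrected MSD estimate, sticky transitions (0.95), jittered restarts
(default 5, best final ELBO wins).  Convergence: relative ELBO change below
10⁻⁸ (default) or 5000 iterations.

A finer sub-frame path discretization (m sub-intervals per frame; exact by
the Brownian-bridge decomposition of the exposure average, with residual
blur coefficient `1/(12 m²)` and a bandwidth-m chain) is implemented via
`path_nodes`.  It is *not* the default for fitting: with one observation per
frame the extra nodes are data-starved, and the factorized posterior's
self-reinforcement worsens state inference as m grows.  The two-point
embedding (m = 1) is the default.

Refined positions target the true shutter-weighted (exposure-averaged)
position of each frame — the quantity the raw localization estimates,
centred `τΔt` into the frame.  The exposure average is the two-point node
combination plus an independent Brownian-bridge residual that is *also* part
of the measurement; its posterior pulls the refined estimate back toward the
raw position by `c_k/(c_k + ε_t²)` with `c_k = β·2D_kΔt` per state.
Without this term, refinement systematically underestimates fast-state
frames (it would discard the bridge part of the signal); with it, RMSE
improves in both states, most strongly for slow states with large errors.
The static-emitter limit reproduces the `ε/√n` averaging law.

Simplified limits: the Kalman variant is the delta-shutter special case
(τ = β = R = 0, pointwise errors kept); the vbSPT-like variant ignores
errors and blur and is implemented directly as a displacement HMM (its EM is
then exact maximum likelihood).

### Model comparison on the binding scenario

On the scripted binding/unbinding scenario (track-level route, 200
replicates) the vbSPT-like limit misclassifies about seven times more frames
than either error-aware model — using pointwise precisions is what matters
when errors vary strongly.  Between the two error-aware models the
difference is marginal, and the Kalman limit comes out insignificantly-to-
slightly ahead of the blur-aware model in mean misclassification (about
0.002 absolute at ~0.025) despite the latter being the better-specified
model.  The cause is the mean-field factorization: the path posterior
absorbs part of the state-dependent blur-residual variance, slightly
weakening fast-state evidence.  This persists under truth-parameter
initialization, and finer path discretization amplifies rather than removes
it.  Parameter estimation is unaffected (the blur-aware model's D estimates
are unbiased; the Kalman limit's need the 1/(1−2R) correction), and the
acceptance test records the classification ordering honestly, including the
clause this scenario does not reproduce.

## Problem sizes

Defaults chosen for the bundled checks: 2000 spots for the precision
calibration; 1200 ten-step trajectories per error level for diffusion
recovery; 100 replicates of 1000 frames for two-state parameter recovery;
200 replicates of 600 frames for the model comparison; 10⁵–10⁶ draws for
the noise-model Monte-Carlo checks.  These sizes give Monte-Carlo errors
comfortably below each check's tolerance.

## Known limitations

* Gaussian spot and Gaussian-beam defocus only; no vectorial/engineered PSFs,
  no experimentally derived PSF models, no 3D localization.
* Spot detection, trajectory linking, gaps/blinking, photobleaching kinetics
  and drift correction are out of scope; seeds and uninterrupted
  trajectories are inputs.
* No model selection over the number of diffusive states K.
* The EMCCD model assumes the high-gain limit and camera-wide noise
  parameters; dark-movie calibration is instrument-specific and not
  included.
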