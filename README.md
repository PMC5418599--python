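# pointloc

Uncertainty-aware single-molecule localization and tracking: maximum a
posteriori (MAP) spot fitting with pointwise precision estimates, and
downstream analyses — diffusion estimation, multi-state segmentation and
position refinement — that actually use those precisions.

## Why

In live-cell localization microscopy and single-particle tracking, the
precision of each fitted position varies strongly from frame to frame:
molecules move during the exposure (motion blur), drift out of focus, and sit
on variable fluorescent background.  Plug-in formulas such as the Cramér–Rao
lower bound (CRLB) describe a best case and can be badly wrong for dim or
defocused spots.  `pointloc` instead estimates the precision of every single
localization from its own image, via the Laplace approximation to the
Bayesian posterior, with weak physics-based priors that keep the fits in the
physically meaningful regime.  It then feeds those pointwise precisions into
diffusion estimators and a blur-aware diffusive hidden Markov model (HMM).

## The models

**Spot images.**  A spot is a pixel-integrated 2D Gaussian: expected photons
in pixel *i* are `E_i = b + N ∫_i g(x, y) dA`, with background *b*
(photons/pixel), amplitude *N* (photons/spot), width σ (or two principal
widths σ₁, σ₂ and an angle φ), and centre (μₓ, μᵧ).  Counts follow an EMCCD
noise model: Poisson photons, exponential (high-gain) EM amplification, and
Gaussian readout noise.

**MAP fitting and precision.**  MLE maximizes `ln L(θ) = Σ_i ln q(c_i|E_i)`;
MAP adds priors: an exponential prior (mean 1) on the dimensionless excess
width `Δσ = (σ − σ₀)/σ₀` above the diffraction-limited width
`σ₀ = 0.21 λ/NA`, and a weak normal prior (s.d. ln 30) on the log
background.  The reparameterization makes `σ > σ₀` structural.  The
pointwise precision is the position standard deviation of the Laplace
(inverse-Hessian) approximation `Σ = [−∂² ln L/∂θ²]⁻¹` at the optimum; the
Rieger–Stallinga CRLB formula (with the EMCCD excess-noise factor 2) is
provided for comparison.

**Diffusion with blur and noise.**  Measured steps of a freely diffusing
particle obey `⟨Δx²⟩ = 2DΔt(1−2R) + 2ε²` and
`⟨Δx_k Δx_{k+1}⟩ = 2RDΔt − ε²`, where the blur coefficient `R ∈ [0, 1/4]`
is set by the shutter (1/6 for continuous illumination) and ε² is the
localization-error variance.  Covariance-based estimators solve these
moments for D, with or without known ε².

**Multi-state HMM.**  Observed positions are shutter-weighted averages of
the true Brownian path plus heteroscedastic Gaussian errors; the diffusion
constant switches between K states via a Markov chain.  A variational EM
algorithm (factorized posterior over states × path, with a monotone evidence
lower bound) infers per-state D, the transition matrix, hidden states, and
refined positions that combine information across frames — often beating the
single-image precision, especially for slow states with noisy localizations.
Kalman-type (no blur) and vbSPT-like (no blur, no errors) limits are
included for comparison, together with the step-variance corrections of
their D estimates.

## Worked example

```python
import math, numpy as np, pointloc as pl

# simulate a 300-frame EMCCD movie of a diffusing emitter (600 photons/spot,
# 1 photon/pixel background, 1 ms continuous exposure, D = 1 um^2/s) ...
scn = pl.SimScenario(frame_interval=0.001, photons=600.0, background=1.0,
                     defocus_scale=0.0, substeps=10)
rng = np.random.default_rng(7)
truth = pl.simulate_path(scn, 300, rng)
stack, seeds = pl.render_movie(scn, truth, rng, window=8)

# ... MAP-localize every spot and compare estimated with true precision
priors = pl.PriorConfig(sigma0=scn.sigma0, log_background_center=math.log(1.0))
table, _ = pl.localize_frames(stack, seeds, scn.camera, mode="map", priors=priors)
```

Comparing the fitted positions against the simulation ground truth prints

```
retained 300/300 spots
RMS true error      : 6.19 nm
RMS Laplace estimate: 6.34 nm
mean CRLB           : 6.61 nm
```

— the per-spot Laplace estimates reproduce the actual error spread to a few
percent.  Feeding trajectories with per-point precisions into the two-state
HMM:

```python
A = np.array([[0.99, 0.01], [0.01, 0.99]])
(obs, tr), = pl.synth_hmm_tracks(2, [0.1, 1.0], A, [0.5, 0.5], dt=0.005,
                                 eps_model=(20.0, 60.0), n_frames=1000,
                                 n_traj=1, seed=3)
model, post = pl.vem_fit(obs, K=2, restarts=5, seed=0)
```

```
fitted D: 0.095 and 0.968 um^2/s (truth 0.1 and 1.0)
dwell probabilities: A[0,0]=0.991, A[1,1]=0.974
misclassification vs ground truth: 4.9%
raw RMSE 40.6 nm -> refined RMSE 24.1 nm
```

The refined positions (posterior means of the true path given all frames and
their precisions) nearly halve the RMSE of the raw localizations here.

## Command line

The same pipeline is available as subcommands, all seeded and reproducible:

```bash
pointloc simulate  --config scenario.yaml --frames 200 --seed 1 \
                   --out movie.tif --truth truth.csv --seeds seeds.csv
pointloc localize  --stack movie.tif --seeds seeds.csv --camera cam.yaml \
                   --mode map --out locs.csv
pointloc diffusion --traj traj.csv --dt 0.005 --estimator cov_eps --out d.csv
pointloc hmm       --traj traj.csv --dt 0.005 --k 2 --variant full \
                   --out model.json --refined refined.csv
pointloc refine    --traj traj.csv --dt 0.005 --model model.json --out refined.csv
```

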