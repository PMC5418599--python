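"""Single-state diffusion estimation from noisy, blurred trajectories.

For a freely diffusing particle imaged with a camera, the measured steps
``dx_k = x_{k+1} - x_k`` are zero-mean Gaussian with

    <dx_k^2>         = 2 D dt (1 - 2R) + 2 eps^2
    <dx_k dx_{k+1}>  = 2 R D dt - eps^2

and uncorrelated at larger lags.  Here ``R`` (in [0, 1/4]) is the motion-blur
coefficient set by the shutter (1/6 for continuous illumination), ``dt`` the
frame interval and ``eps^2`` the localization-error variance.  Combining the
two sample moments eliminates both nuisance terms (``d_cov``); if ``eps^2``
is known, e.g. averaged from pointwise precision estimates, the first moment
alone gives a lower-variance estimator (``d_cov_eps``).  A full
likelihood-based estimator with pointwise errors is available through the
single-state limit of the diffusive HMM (``mle_diffusion``).

Lengths are nm, times seconds, diffusion constants um^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Trajectory",
    "StepStats",
    "step_stats",
    "d_cov",
    "d_cov_eps",
    "mle_diffusion",
    "correct_D",
]

NM2_PER_UM2 = 1.0e6


@dataclass
class Trajectory:
    """Uniformly sampled positions (nm) with optional per-point precisions.

    ``positions`` has shape (T, n_axes); ``eps2`` (same shape, nm^2) holds the
    localization-error variances if available.  ``R`` is the blur coefficient
    of the acquisition (0 <= R <= 1/4).
    """

    positions: np.ndarray
    dt: float
    eps2: np.ndarray | None = None
    R: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] == 1 and self.positions.shape[1] > 2:
            self.positions = self.positions.T
        if len(self.positions) < 2:
            raise ValueError("trajectory needs at least 2 points")
        if not (0.0 <= self.R <= 0.25):
            raise ValueError("blur coefficient R must lie in [0, 1/4]")
        if self.eps2 is not None:
            self.eps2 = np.atleast_2d(np.asarray(self.eps2, dtype=float))
            if self.eps2.shape[0] == 1 and self.eps2.shape[1] > 2:
                self.eps2 = self.eps2.T
            if self.eps2.shape != self.positions.shape:
                raise ValueError("eps2 must match positions in shape")
            if np.any(self.eps2 < 0):
                raise ValueError("eps2 must be >= 0")

    @property
    def mean_eps2(self) -> float:
        if self.eps2 is None:
            raise ValueError("trajectory carries no precision estimates")
        return float(np.mean(self.eps2))


@dataclass
class StepStats:
    """Pooled step moments: mean square step and lag-1 step covariance (nm^2)."""

    msd: float
    lag1: float
    n_steps: int
    n_pairs: int


def step_stats(traj: Trajectory) -> StepStats:
    """Sample step moments pooled across axes (lag-1 needs >= 3 points)."""
    x = traj.positions
    if len(x) < 3:
        raise ValueError("need at least 3 points for lag-1 step covariance")
    dx = np.diff(x, axis=0)
    msd = float(np.mean(dx**2))
    lag1 = float(np.mean(dx[:-1] * dx[1:]))
    return StepStats(msd=msd, lag1=lag1, n_steps=dx.size, n_pairs=dx[:-1].size)


def d_cov(stats: StepStats, dt: float) -> float:
    """Covariance-based estimator <dx^2>/(2 dt) + <dx_k dx_{k+1}>/dt (um^2/s).

    Eliminates both blur and localization error without external input.  May
    be negative on noisy data; values are reported as-is so ensemble means
    stay unbiased.
    """
    return (stats.msd / (2.0 * dt) + stats.lag1 / dt) / NM2_PER_UM2


def d_cov_eps(stats: StepStats, dt: float, R: float, mean_eps2: float) -> float:
    """Improved estimator (<dx^2> - 2 eps2_bar) / (2 dt (1 - 2R)) (um^2/s).

    Uses the known (average) localization-error variance ``mean_eps2`` (nm^2)
    and blur coefficient ``R``.
    """
    if not (0.0 <= R <= 0.25):
        raise ValueError("R must lie in [0, 1/4]")
    return (stats.msd - 2.0 * mean_eps2) / (2.0 * dt * (1.0 - 2.0 * R)) / NM2_PER_UM2


def mle_diffusion(traj: Trajectory, tau: float | None = None, beta: float | None = None,
                  **opts):
    """Likelihood-based D estimate using pointwise precisions.

    Runs the single-state limit of the diffusive HMM (where the variational
    factorization is exact) on the trajectory, returning
    ``(D_hat um^2/s, posterior path mean, log-likelihood)``.  ``tau``/``beta``
    default to the values implied by the trajectory's blur coefficient
    (``tau = 1/2, beta = 1/4 - R``; the delta-shutter case R = 0 uses
    ``tau = beta = 0``).
    """
    from .hmm import Observations, vem_fit

    if traj.eps2 is None:
        raise ValueError("mle_diffusion requires per-point precisions (eps2)")
    if tau is None or beta is None:
        if traj.R == 0.0:
            tau, beta = 0.0, 0.0
        else:
            tau, beta = 0.5, 0.25 - traj.R
    obs = Observations(x=traj.positions, v=traj.eps2, dt=traj.dt)
    model, post = vem_fit(obs, K=1, tau=tau, beta=beta, restarts=1, **opts)
    return float(model.D[0]), post.y_mean, float(post.elbo_trace[-1])


def correct_D(D_fit: float, model: str, R: float, mean_eps2: float, dt: float) -> float:
    """Heuristic blur/noise correction of a simplified-model D estimate.

    Equates step-length variances with and without the neglected effects:
    ``kalman`` (errors modelled, blur not): D* = D_fit / (1 - 2R);
    ``vbspt`` (neither modelled): D* = (D_fit - eps2_bar/dt) / (1 - 2R),
    with ``mean_eps2`` in nm^2.
    """
    if model not in ("kalman", "vbspt"):
        raise ValueError("model must be 'kalman' or 'vbspt'")
    if model == "kalman":
        return D_fit / (1.0 - 2.0 * R)
    return (D_fit - mean_eps2 / dt / NM2_PER_UM2) / (1.0 - 2.0 * R)
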