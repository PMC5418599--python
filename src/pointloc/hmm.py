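"""Multi-state diffusive HMM with pointwise localization errors and blur.

The observation model (per axis, all lengths nm) treats each measured
position as a shutter-weighted average of the true Brownian path ``y(t)``
plus heteroscedastic Gaussian localization noise.  Discretizing the path at
the frame boundaries ``y_t`` gives the two-point embedding

    x_t   = (1 - tau) y_t + tau y_{t+1} + eta_t,
    eta_t ~ N(0, v_t + 2 D_{s_t} dt * beta),
    y_{t+1} = y_t + w_t,          w_t ~ N(0, 2 D_{s_t} dt),

where ``v_t = eps_t^2`` is the localization-error variance of frame ``t``,
``s_t`` the hidden diffusive state of interval ``t -> t+1`` (a Markov chain
with transition matrix ``A``), ``tau`` the first moment of the normalized
shutter function and ``beta = tau (1 - tau) - R`` its variance coefficient.
This embedding reproduces the step-covariance structure of camera-based
tracking exactly: <dx^2> = 2 D dt (1-2R) + 2 eps^2, <dx_k dx_{k+1}> =
2 R D dt - eps^2, zero at larger lags.

Inference is variational EM with the factorized posterior q(s) q(y):
discrete forward-backward for the states, Gaussian chain message passing
(tridiagonal precision) for the path, and M-steps for ``D_k``, ``A``,
``pi``.  The evidence lower bound (ELBO) is monotone by construction and is
checked at every iteration.  For K = 1 the factorization is exact and the
converged ELBO equals the marginal log-likelihood.

Special cases: a delta-function shutter gives tau = beta = R = 0 (a
Kalman-type model with errors but no blur); additionally forcing v = 0
yields a plain displacement HMM that ignores localization errors (the
vbSPT-like limit), implemented on the displacements directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar

__all__ = [
    "Observations",
    "DiffusiveHMM",
    "HMMPosterior",
    "blur_constants",
    "vem_fit",
    "limit_fit",
    "classify",
    "misclassification",
    "refine_positions",
    "synth_hmm_tracks",
]

NM2_PER_UM2 = 1.0e6
D_MIN, D_MAX = 1.0e-7, 1.0e4  # um^2/s bounds for the M-step search


@dataclass
class Observations:
    """Uninterrupted 2D trajectory: positions x (T, 2) nm, error variances
    v = eps^2 (T, 2) nm^2, frame interval dt in seconds."""

    x: np.ndarray
    v: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.v = np.atleast_2d(np.asarray(self.v, dtype=float))
        if self.x.shape[1] != 2:
            raise ValueError("observations must have two axes (T, 2)")
        if self.v.shape != self.x.shape:
            raise ValueError("v must match x in shape")
        if np.any(self.v < 0):
            raise ValueError("error variances must be >= 0")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")

    def __len__(self) -> int:
        return self.x.shape[0]


@dataclass
class DiffusiveHMM:
    """Fitted model: per-state D (um^2/s, ascending), transition matrix A,
    initial distribution pi, and the shutter constants (R, tau, beta)."""

    K: int
    D: np.ndarray
    A: np.ndarray
    pi: np.ndarray
    dt: float
    tau: float
    beta: float
    R: float
    converged: bool = True

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.D <= 0):
            raise ValueError("diffusion constants must be > 0")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of A must sum to 1")
        if not math.isclose(self.pi.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("pi must sum to 1")
        if self.beta < -1e-12:
            raise ValueError("beta must be >= 0")


@dataclass
class HMMPosterior:
    """Variational posterior: state marginals gamma (T, K), pairwise xi
    (T-1, K, K), Gaussian path marginals per axis (at the path-node
    resolution of the fit, m*T + 1 nodes), refined per-frame positions at
    the shutter's first-moment time, and the ELBO trace."""

    gamma: np.ndarray
    xi: np.ndarray
    y_mean: np.ndarray
    y_var: np.ndarray
    y_cov1: np.ndarray
    refined_mean: np.ndarray
    refined_sd: np.ndarray
    elbo_trace: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# shutter -> blur constants


def _shutter_atoms(shutter, n_grid=4097):
    """Normalize a shutter spec to point masses (times on [0,1], weights)."""
    if isinstance(shutter, str):
        if shutter in ("continuous", "uniform"):
            t = np.linspace(0.0, 1.0, n_grid)
            w = np.ones(n_grid)
        elif shutter in ("delta", "delta-start", "instantaneous"):
            t = np.array([0.0])
            w = np.array([1.0])
        elif shutter == "two-impulse":
            t = np.array([0.0, 1.0])
            w = np.array([0.5, 0.5])
        else:
            raise ValueError(f"unknown shutter '{shutter}'")
    elif callable(shutter):
        t = np.linspace(0.0, 1.0, n_grid)
        w = np.asarray([float(shutter(ti)) for ti in t])
    else:
        w = np.asarray(shutter, dtype=float).ravel()
        t = np.linspace(0.0, 1.0, w.size) if w.size > 1 else np.array([0.0])
    if np.any(w < 0):
        raise ValueError("shutter weights must be non-negative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("shutter must have positive total weight")
    return t, w / tot


def blur_constants(shutter="continuous", n_grid=4097):
    """Blur constants (R, tau, beta) of a normalized shutter on [0, dt].

    ``R = (1/dt) int S(t)(1 - S(t)) dt`` with ``S`` the cumulative shutter,
    ``tau`` the shutter's first moment (in units of dt) and
    ``beta = tau (1 - tau) - R``; for this triple the two-point state-space
    embedding reproduces the step covariances of the blurred-observation
    model exactly.  Accepts 'continuous', 'delta', 'two-impulse', a callable
    density on [0, 1], or an array of point-mass weights on a uniform grid.
    """
    if isinstance(shutter, str) and shutter in ("continuous", "uniform"):
        # closed form for the constant shutter f(t) = 1/dt
        return 1.0 / 6.0, 0.5, 1.0 / 12.0
    t, w = _shutter_atoms(shutter, n_grid)
    tau = float(np.sum(t * w))
    S = np.cumsum(w)
    # S is piecewise constant between atoms: R = sum over gaps of S(1-S) dt
    if t.size > 1:
        gaps = np.diff(t)
        Smid = S[:-1]
        R = float(np.sum(gaps * Smid * (1.0 - Smid)))
    else:
        R = 0.0
    beta = tau * (1.0 - tau) - R
    if beta < -1e-9:
        raise ValueError(f"invalid shutter: beta = {beta} < 0")
    return R, tau, max(beta, 0.0)


# ---------------------------------------------------------------------------
# numba kernels: Gaussian chain and discrete forward-backward


@njit(cache=True)
def _band_chain(Jb, h):
    """Banded LDL' factorization, solve, and Takahashi inverse recursion.

    ``Jb`` stores the SPD banded precision in lower form, ``Jb[k, i] =
    J[i+k, i]`` for offsets ``k = 0..bw``.  Returns the mean ``J^{-1} h``,
    the in-band covariance entries ``Sb`` (same layout), and ``log det J``.
    """
    bw, n = Jb.shape[0] - 1, Jb.shape[1]
    Lb = np.zeros((bw, n))  # Lb[k-1, j] = L[j+k, j], unit lower triangular
    d = np.zeros(n)
    for i in range(n):
        s = Jb[0, i]
        j0 = i - bw if i - bw > 0 else 0
        for j in range(j0, i):
            s -= Lb[i - j - 1, j] * Lb[i - j - 1, j] * d[j]
        d[i] = s
        for k in range(1, bw + 1):
            if i + k < n:
                s = Jb[k, i]
                j0 = i + k - bw if i + k - bw > 0 else 0
                for j in range(j0, i):
                    s -= Lb[i + k - j - 1, j] * Lb[i - j - 1, j] * d[j]
                Lb[k - 1, i] = s / d[i]
    # solve L z = h, then D w = z, then L' mu = w
    z = h.copy()
    for j in range(n):
        for k in range(1, bw + 1):
            if j + k < n:
                z[j + k] -= Lb[k - 1, j] * z[j]
    mu = np.empty(n)
    for i in range(n - 1, -1, -1):
        s = z[i] / d[i]
        for k in range(1, bw + 1):
            if i + k < n:
                s -= Lb[k - 1, i] * mu[i + k]
        mu[i] = s
    # Takahashi equations for the in-band inverse entries
    Sb = np.zeros((bw + 1, n))
    logdet = 0.0
    for j in range(n - 1, -1, -1):
        logdet += np.log(d[j])
        imax = j + bw if j + bw < n - 1 else n - 1
        for i in range(imax, j - 1, -1):
            s = 1.0 / d[j] if i == j else 0.0
            for k in range(j + 1, j + bw + 1):
                if k < n:
                    # sigma(i, k), |i - k| <= bw by construction
                    if i >= k:
                        s -= Lb[k - j - 1, j] * Sb[i - k, k]
                    else:
                        s -= Lb[k - j - 1, j] * Sb[k - i, i]
            Sb[i - j, j] = s
    return mu, Sb, logdet


@njit(cache=True)
def _forward_backward(log_rho, A, pi):
    """Scaled forward-backward.  Returns (gamma, xi, ln Z)."""
    T, K = log_rho.shape
    shift = np.empty(T)
    rho = np.empty((T, K))
    for t in range(T):
        m = log_rho[t, 0]
        for k in range(1, K):
            if log_rho[t, k] > m:
                m = log_rho[t, k]
        shift[t] = m
        for k in range(K):
            rho[t, k] = np.exp(log_rho[t, k] - m)
    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * rho[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * A[j, k]
            alpha[t, k] = acc * rho[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s
    beta_ = np.ones((T, K))
    for t in range(T - 2, -1, -1):
        for j in range(K):
            acc = 0.0
            for k in range(K):
                acc += A[j, k] * rho[t + 1, k] * beta_[t + 1, k]
            beta_[t, j] = acc / c[t + 1]
    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta_[t, k]
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s
    xi = np.empty((T - 1, K, K))
    for t in range(T - 1):
        s = 0.0
        for j in range(K):
            for k in range(K):
                xi[t, j, k] = alpha[t, j] * A[j, k] * rho[t + 1, k] * beta_[t + 1, k]
                s += xi[t, j, k]
        for j in range(K):
            for k in range(K):
                xi[t, j, k] /= s
    lnZ = 0.0
    for t in range(T):
        lnZ += np.log(c[t]) + shift[t]
    return gamma, xi, lnZ


# ---------------------------------------------------------------------------
# variational EM


def _node_weights(tau: float, beta: float, m: int):
    """Observation weights over the m+1 path nodes of a frame, and the
    residual blur-variance coefficient.

    For m == 1 this is the two-point embedding ``((1-tau), tau)`` with the
    shutter's beta.  For m > 1 (continuous illumination only) the exposure
    average decomposes exactly over the sub-nodes with trapezoid weights,
    leaving a Brownian-bridge residual with coefficient ``1/(12 m^2)``.
    """
    if m == 1:
        return np.array([1.0 - tau, tau]), beta
    if not (abs(tau - 0.5) < 1e-9 and abs(beta - 1.0 / 12.0) < 1e-9):
        raise ValueError("path refinement (m > 1) requires the continuous shutter")
    w = np.full(m + 1, 1.0 / m)
    w[0] = w[-1] = 0.5 / m
    return w, 1.0 / (12.0 * m * m)


def _estep_path(x, v, gamma, sig2, w, beta_m, m):
    """E-step for q(y) on one axis at path discretization m.

    Returns (mu, Sb, logdet, S_step, mu_obs, quad_obs): the banded Gaussian
    posterior, the per-frame expected squared sub-step sums, and the
    posterior mean/variance of the shutter-weighted node combination (the
    quantity the raw localization estimates).
    """
    T = x.shape[0]
    n = m * T + 1
    p_sub = np.repeat(gamma @ (m / sig2), m)  # (mT,) E_q[1 / sub-step var]
    omega = (gamma / (v[:, None] + beta_m * sig2[None, :])).sum(axis=1)  # (T,)
    Jb = np.zeros((m + 1, n))
    h = np.zeros(n)
    Jb[0, :-1] += p_sub
    Jb[0, 1:] += p_sub
    Jb[1, : n - 1] -= p_sub
    base = np.arange(T) * m
    for a in range(m + 1):
        h[base + a] += omega * x * w[a]
        for b in range(a + 1):
            Jb[a - b, base + b] += omega * w[a] * w[b]
    mu, Sb, logdet = _band_chain(Jb, h)

    dmu = np.diff(mu)
    step_e = dmu**2 + Sb[0, :-1] + Sb[0, 1:] - 2.0 * Sb[1, : n - 1]
    S_step = step_e.reshape(T, m).sum(axis=1)
    mu_obs = np.zeros(T)
    quad = np.zeros(T)
    for a in range(m + 1):
        mu_obs += w[a] * mu[base + a]
        quad += w[a] * w[a] * Sb[0, base + a]
        for b in range(a):
            quad += 2.0 * w[a] * w[b] * Sb[a - b, base + b]
    return mu, Sb, logdet, S_step, mu_obs, quad


def _log_rho(v, sig2, beta_m, m, s_step, s_obs):
    """Expected per-frame log emission for each state, both axes summed."""
    T = v.shape[0]
    K = sig2.shape[0]
    out = np.zeros((T, K))
    ln2pi = math.log(2.0 * math.pi)
    log_subvar = np.log(sig2 / m)
    for ax in range(2):
        obs_var = v[:, ax, None] + beta_m * sig2[None, :]
        out -= 0.5 * (
            s_step[:, ax, None] * (m / sig2)[None, :]
            + m * (ln2pi + log_subvar)[None, :]
            + s_obs[:, ax, None] / obs_var
            + ln2pi
            + np.log(obs_var)
        )
    return out


def _mstep_sig2(gamma, v, beta_m, m, s_step, s_obs, sig2_old, sig2_lo, sig2_hi):
    """Maximize the expected complete-data log-likelihood over sigma2_k.

    Closed form for beta_m = 0; otherwise bounded scalar search in log
    sigma2, guarded so the objective never decreases (generalized EM).
    """
    K = gamma.shape[1]
    sig2_new = np.empty(K)
    for k in range(K):
        g = gamma[:, k]
        n_eff = 2.0 * g.sum()  # two axes
        a_step = float(g @ s_step.sum(axis=1))
        if beta_m == 0.0:
            sig2_new[k] = np.clip(a_step / max(n_eff, 1e-300), sig2_lo, sig2_hi)
            continue

        def neg(ls2, g=g, a_step=a_step, n_eff=n_eff):
            s2 = math.exp(ls2)
            obs_var = v + beta_m * s2  # (T, 2)
            val = a_step * m / (2.0 * s2) + 0.5 * m * n_eff * math.log(s2)
            val += 0.5 * float(
                g @ (s_obs / obs_var + np.log(obs_var)).sum(axis=1)
            )
            return val

        res = minimize_scalar(
            neg,
            bounds=(math.log(sig2_lo), math.log(sig2_hi)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun <= neg(math.log(sig2_old[k])):
            sig2_new[k] = math.exp(res.x)
        else:
            sig2_new[k] = sig2_old[k]
    return sig2_new


def _run_vem(obs, K, tau, beta, m, D0, A0, pi0, max_iter, tol):
    """One EM run from a given initialization.  Returns (params, posterior bits)."""
    x, v, dt = obs.x, obs.v, obs.dt
    T = len(obs)
    w, beta_m = _node_weights(tau, beta, m)
    sig2 = 2.0 * D0 * NM2_PER_UM2 * dt  # nm^2 per state
    sig2_lo = 2.0 * D_MIN * NM2_PER_UM2 * dt
    sig2_hi = 2.0 * D_MAX * NM2_PER_UM2 * dt
    A = A0.copy()
    pi = pi0.copy()
    gamma = np.full((T, K), 1.0 / K)
    v_eff = np.maximum(v, 1e-12)  # zero-error observations: tiny floor

    elbo_trace = []
    elbo_prev = -np.inf
    chains = [None, None]
    xi = None
    n_nodes = m * T + 1
    for _ in range(max_iter):
        # E-step, q(y) per axis
        s_step = np.empty((T, 2))
        s_obs = np.empty((T, 2))
        H_y = 0.0
        for ax in range(2):
            mu, Sb, logdet, S_step, mu_obs, quad = _estep_path(
                x[:, ax], v_eff[:, ax], gamma, sig2, w, beta_m, m
            )
            chains[ax] = (mu, Sb, mu_obs, quad)
            s_step[:, ax] = S_step
            s_obs[:, ax] = (x[:, ax] - mu_obs) ** 2 + quad
            H_y += 0.5 * n_nodes * (1.0 + math.log(2.0 * math.pi)) - 0.5 * logdet
        # E-step, q(s)
        log_rho = _log_rho(v_eff, sig2, beta_m, m, s_step, s_obs)
        gamma, xi, lnZ = _forward_backward(log_rho, A, pi)
        elbo = lnZ + H_y
        elbo_trace.append(elbo)
        if abs(elbo - elbo_prev) <= tol * max(abs(elbo), 1.0):
            elbo_prev = elbo
            break
        elbo_prev = elbo
        # M-step
        pi = gamma[0] / gamma[0].sum()
        xis = xi.sum(axis=0)
        rows = xis.sum(axis=1, keepdims=True)
        A = np.where(rows > 0, xis / np.maximum(rows, 1e-300), 1.0 / K)
        A /= A.sum(axis=1, keepdims=True)
        sig2 = _mstep_sig2(
            gamma, v_eff, beta_m, m, s_step, s_obs, sig2, sig2_lo, sig2_hi
        )

    D = sig2 / (2.0 * dt) / NM2_PER_UM2
    return D, A, pi, gamma, xi, chains, np.asarray(elbo_trace)


def _init_params(K, D_scale, A_diag, rng, jitter):
    if K == 1:
        D0 = np.array([D_scale * math.exp(jitter * rng.standard_normal())])
    else:
        # states bracket the trajectory-average D
        D0 = D_scale * np.logspace(math.log10(0.2), math.log10(2.0), K)
        if jitter > 0:
            D0 = D0 * np.exp(jitter * rng.standard_normal(K))
    D0 = np.clip(D0, D_MIN * 10, D_MAX / 10)
    A0 = np.full((K, K), (1.0 - A_diag) / max(K - 1, 1))
    np.fill_diagonal(A0, A_diag if K > 1 else 1.0)
    pi0 = np.full(K, 1.0 / K)
    return D0, A0, pi0


def vem_fit(
    obs: Observations,
    K: int,
    restarts: int = 5,
    max_iter: int = 5000,
    tol: float = 1e-8,
    seed: int | None = None,
    shutter=None,
    tau: float | None = None,
    beta: float | None = None,
    init_D=None,
    path_nodes: int | None = None,
):
    """Variational-EM fit of the K-state diffusive HMM.

    The shutter may be given directly (``shutter=`` as accepted by
    :func:`blur_constants`, default continuous illumination) or via explicit
    ``tau``/``beta``.  ``path_nodes`` sets the number of path sub-intervals
    per frame (default 1: the two-point embedding, which is exact in
    covariance; finer discretizations are available for the continuous
    shutter but amplify the factorized posterior's self-reinforcement and
    are mainly useful for path refinement).  The best of ``restarts`` seeded
    initializations is returned, with states sorted by ascending D.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(obs) < K + 2:
        raise ValueError("trajectory too short for the requested K")
    if tau is None or beta is None:
        R, tau, beta = blur_constants(shutter if shutter is not None else "continuous")
    else:
        R = tau * (1.0 - tau) - beta
    m = 1 if path_nodes is None else int(path_nodes)
    rng = np.random.default_rng(seed)
    dx = np.diff(obs.x, axis=0)
    msd = float(np.mean(dx**2))
    # noise- and blur-corrected scale for the initial D values
    msd_corr = (msd - 2.0 * float(np.mean(obs.v))) / max(1.0 - 2.0 * R, 0.5)
    if msd_corr <= 0:
        msd_corr = 0.25 * msd
    D_scale = max(msd_corr / (2.0 * obs.dt) / NM2_PER_UM2, 10 * D_MIN)

    best = None
    for r in range(restarts):
        if init_D is not None:
            D0 = np.asarray(init_D, dtype=float)
            if r > 0:
                D0 = D0 * np.exp(0.2 * rng.standard_normal(K))
            A0 = np.full((K, K), 0.05 / max(K - 1, 1))
            np.fill_diagonal(A0, 0.95 if K > 1 else 1.0)
            pi0 = np.full(K, 1.0 / K)
        else:
            D0, A0, pi0 = _init_params(K, D_scale, 0.95, rng, 0.0 if r == 0 else 0.3)
        out = _run_vem(obs, K, tau, beta, m, D0, A0, pi0, max_iter, tol)
        if best is None or out[6][-1] > best[6][-1]:
            best = out
    D, A, pi, gamma, xi, chains, elbo_trace = best

    order = np.argsort(D)
    D, pi = D[order], pi[order]
    A = A[np.ix_(order, order)]
    gamma = gamma[:, order]
    xi = xi[:, order][:, :, order]

    model = DiffusiveHMM(
        K=K, D=D, A=A, pi=pi / pi.sum(), dt=obs.dt, tau=tau, beta=beta, R=R,
        converged=True,
    )
    sig2 = 2.0 * D * NM2_PER_UM2 * obs.dt
    _, beta_m = _node_weights(tau, beta, m)
    post = _build_posterior(obs, gamma, xi, chains, sig2, beta_m, elbo_trace)
    return model, post


def _build_posterior(obs, gamma, xi, chains, sig2, beta_m, elbo_trace):
    """Assemble the posterior; refined positions target the true
    shutter-weighted (exposure-averaged) position of each frame.

    The exposure average decomposes into the node combination ``w . y`` plus
    an independent blur residual of variance ``c_k = beta_m sig2_k`` that is
    also part of the observation; its posterior pulls the refined estimate
    back toward the measurement by ``c_k / (c_k + v_t)`` per state.
    """
    # chains[ax] = (node means, banded covariance, w.mu per frame, w'Sigma w)
    y_mean = np.column_stack([chains[ax][0] for ax in range(2)])
    y_var = np.column_stack([chains[ax][1][0] for ax in range(2)])
    y_cov1 = np.column_stack([chains[ax][1][1][:-1] for ax in range(2)])
    v_eff = np.maximum(obs.v, 1e-12)
    ref_mean = np.empty_like(obs.x)
    ref_var = np.empty_like(obs.x)
    for ax in range(2):
        mu_obs, quad = chains[ax][2], chains[ax][3]
        x = obs.x[:, ax]
        chat = beta_m * sig2[None, :] / (beta_m * sig2[None, :] + v_eff[:, ax, None])
        mean_k = mu_obs[:, None] + chat * (x - mu_obs)[:, None]  # (T, K)
        var_k = (1.0 - chat) ** 2 * quad[:, None] + chat * v_eff[:, ax, None]
        ref_mean[:, ax] = np.sum(gamma * mean_k, axis=1)
        ref_var[:, ax] = np.sum(
            gamma * (var_k + (mean_k - ref_mean[:, ax, None]) ** 2), axis=1
        )
    return HMMPosterior(
        gamma=gamma,
        xi=xi,
        y_mean=y_mean,
        y_var=y_var,
        y_cov1=y_cov1,
        refined_mean=ref_mean,
        refined_sd=np.sqrt(np.maximum(ref_var, 0.0)),
        elbo_trace=elbo_trace,
    )


# ---------------------------------------------------------------------------
# simplified limits


def _fit_displacement_hmm(obs, K, restarts, max_iter, tol, seed):
    """vbSPT-like limit: HMM directly on displacements, no errors, no blur."""
    x, dt = obs.x, obs.dt
    d = np.diff(x, axis=0)  # (T-1, 2)
    Tm1 = d.shape[0]
    rng = np.random.default_rng(seed)
    D_scale = max(float(np.mean(d**2)) / (2.0 * dt) / NM2_PER_UM2, 10 * D_MIN)
    d2 = (d**2).sum(axis=1)
    ln2pi = math.log(2.0 * math.pi)

    best = None
    for r in range(restarts):
        D0, A, pi = _init_params(K, D_scale, 0.95, rng, 0.0 if r == 0 else 0.3)
        sig2 = 2.0 * D0 * NM2_PER_UM2 * dt
        elbo_trace = []
        prev = -np.inf
        for _ in range(max_iter):
            log_rho = -0.5 * (
                d2[:, None] / sig2[None, :] + 2.0 * (ln2pi + np.log(sig2))[None, :]
            )
            gamma, xi, lnZ = _forward_backward(log_rho, A, pi)
            elbo_trace.append(lnZ)
            if abs(lnZ - prev) <= tol * max(abs(lnZ), 1.0):
                break
            prev = lnZ
            pi = gamma[0] / gamma[0].sum()
            xis = xi.sum(axis=0)
            A = xis / np.maximum(xis.sum(axis=1, keepdims=True), 1e-300)
            A /= A.sum(axis=1, keepdims=True)
            w = gamma.sum(axis=0)
            sig2 = np.clip(
                (gamma.T @ d2) / np.maximum(2.0 * w, 1e-300),
                2.0 * D_MIN * NM2_PER_UM2 * dt,
                2.0 * D_MAX * NM2_PER_UM2 * dt,
            )
        cand = (sig2 / (2.0 * dt) / NM2_PER_UM2, A, pi, gamma, xi, np.asarray(elbo_trace))
        if best is None or cand[5][-1] > best[5][-1]:
            best = cand
    D, A, pi, gamma, xi, elbo_trace = best
    order = np.argsort(D)
    D, pi = D[order], pi[order]
    A = A[np.ix_(order, order)]
    gamma = gamma[:, order]
    xi = xi[:, order][:, :, order]
    # interval states: pad the last frame with the last interval's marginal
    gamma_frames = np.vstack([gamma, gamma[-1]])
    xi_f = xi
    model = DiffusiveHMM(
        K=K, D=D, A=A, pi=pi / pi.sum(), dt=dt, tau=0.0, beta=0.0, R=0.0
    )
    post = HMMPosterior(
        gamma=gamma_frames,
        xi=xi_f,
        y_mean=x.copy(),
        y_var=obs.v.copy(),
        y_cov1=np.zeros((len(obs) - 1, 2)),
        refined_mean=x.copy(),
        refined_sd=np.sqrt(obs.v),
        elbo_trace=elbo_trace,
    )
    return model, post


def limit_fit(obs: Observations, K: int, variant: str, **opts):
    """Simplified-model fits: 'kalman' (errors, no blur) or 'vbspt' (neither)."""
    if variant == "kalman":
        return vem_fit(obs, K, tau=0.0, beta=0.0, **opts)
    if variant == "vbspt":
        return _fit_displacement_hmm(
            obs,
            K,
            restarts=opts.get("restarts", 5),
            max_iter=opts.get("max_iter", 5000),
            tol=opts.get("tol", 1e-8),
            seed=opts.get("seed"),
        )
    raise ValueError("variant must be 'kalman' or 'vbspt'")


# ---------------------------------------------------------------------------
# classification and refinement


def classify(posterior: HMMPosterior) -> np.ndarray:
    """Most probable state per frame (argmax of the state marginals)."""
    return np.argmax(posterior.gamma, axis=1)


def misclassification(pred_states, true_states) -> float:
    """Fraction of frames whose most probable state differs from the truth.

    Both sequences must use the same ascending-D state labelling.
    """
    pred = np.asarray(pred_states)
    true = np.asarray(true_states)
    n = min(len(pred), len(true))
    return float(np.mean(pred[:n] != true[:n]))


def refine_positions(obs: Observations, model: DiffusiveHMM, max_iter: int = 100,
                     tol: float = 1e-10, path_nodes: int | None = None):
    """Posterior-refined positions under a fitted model (parameters fixed).

    Iterates the two E-steps to convergence and returns the posterior mean
    and s.d. of the shutter-weighted true position of each frame (the
    quantity the raw localization estimates, centred at the shutter's first
    moment ``tau * dt`` into the frame).  Shapes (T, 2).
    """
    K = model.K
    sig2 = 2.0 * model.D * NM2_PER_UM2 * model.dt
    v_eff = np.maximum(obs.v, 1e-12)
    T = len(obs)
    gamma = np.full((T, K), 1.0 / K)
    tau, beta = model.tau, model.beta
    m = 1 if path_nodes is None else int(path_nodes)
    w, beta_m = _node_weights(tau, beta, m)
    prev = -np.inf
    for _ in range(max_iter):
        chains = []
        s_step = np.empty((T, 2))
        s_obs = np.empty((T, 2))
        for ax in range(2):
            mu, Sb, _, S_step, mu_obs, quad = _estep_path(
                obs.x[:, ax], v_eff[:, ax], gamma, sig2, w, beta_m, m
            )
            chains.append((mu, Sb, mu_obs, quad))
            s_step[:, ax] = S_step
            s_obs[:, ax] = (obs.x[:, ax] - mu_obs) ** 2 + quad
        log_rho = _log_rho(v_eff, sig2, beta_m, m, s_step, s_obs)
        gamma, xi, lnZ = _forward_backward(log_rho, model.A, model.pi)
        if abs(lnZ - prev) <= tol * max(abs(lnZ), 1.0):
            break
        prev = lnZ
    post = _build_posterior(obs, gamma, xi, chains, sig2, beta_m, np.array([lnZ]))
    return post.refined_mean, post.refined_sd


# ---------------------------------------------------------------------------
# direct track generator (bypasses image rendering)


def synth_hmm_tracks(
    K: int,
    D,
    A,
    pi,
    dt: float,
    shutter="continuous",
    eps_model=30.0,
    n_frames: int = 1000,
    n_traj: int = 1,
    seed=None,
    substeps: int = 50,
):
    """Exact simulation of the blurred, noisy multi-state diffusion model.

    The true path is sub-stepped Brownian motion whose diffusion constant is
    set per frame interval by a Markov state sequence; each observation is
    the shutter-weighted average of the sub-step positions plus Gaussian
    localization noise with s.d. drawn from ``eps_model`` (a scalar, a
    (lo, hi) uniform range, or a callable ``(rng, states) -> (T, 2)`` nm).

    Returns a list of (Observations, truth) pairs, where truth is a dict
    with the state sequence, the exposure-averaged true positions ``y_avg``
    and the frame-boundary path nodes ``y_nodes``.
    """
    D = np.asarray(D, dtype=float)
    A = np.atleast_2d(np.asarray(A, dtype=float))
    pi = np.asarray(pi, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # shutter weights on the substeps+1 path nodes of each frame interval;
    # the trapezoid rule keeps the implied (R, tau) second-order accurate
    n_nodes = substeps + 1
    if isinstance(shutter, str) and shutter in ("continuous", "uniform"):
        w_sub = np.ones(n_nodes)
        w_sub[0] = w_sub[-1] = 0.5
    elif isinstance(shutter, str) and shutter in ("delta", "delta-start", "instantaneous"):
        w_sub = np.zeros(n_nodes)
        w_sub[0] = 1.0
    elif isinstance(shutter, str) and shutter == "two-impulse":
        w_sub = np.zeros(n_nodes)
        w_sub[0] = w_sub[-1] = 0.5
    else:
        t_atoms, w_atoms = _shutter_atoms(shutter)
        w_sub = np.interp(np.linspace(0, 1, n_nodes), t_atoms, w_atoms)
    w_sub = w_sub / w_sub.sum()

    out = []
    for _ in range(n_traj):
        states = np.empty(n_frames, dtype=np.int64)
        states[0] = rng.choice(K, p=pi)
        for t in range(1, n_frames):
            states[t] = rng.choice(K, p=A[states[t - 1]])
        sig2_sub = 2.0 * D[states] * NM2_PER_UM2 * dt / substeps  # per substep, nm^2
        steps = rng.standard_normal((n_frames, substeps, 2)) * np.sqrt(
            sig2_sub
        )[:, None, None]
        incr = steps.reshape(n_frames * substeps, 2)
        path = np.vstack([np.zeros((1, 2)), np.cumsum(incr, axis=0)])
        # node j of frame t is the position at time (t + j/substeps) * dt
        idx = np.arange(n_frames)[:, None] * substeps + np.arange(n_nodes)[None, :]
        sub_pos = path[idx]  # (n_frames, substeps+1, 2)
        y_avg = np.einsum("s,tsa->ta", w_sub, sub_pos)
        y_nodes = path[::substeps]

        if callable(eps_model):
            eps = np.asarray(eps_model(rng, states), dtype=float)
        elif np.isscalar(eps_model):
            eps = np.full((n_frames, 2), float(eps_model))
        else:
            lo, hi = eps_model
            eps = rng.uniform(lo, hi, size=(n_frames, 1)) * np.ones((1, 2))
        x = y_avg + rng.standard_normal((n_frames, 2)) * eps
        obs = Observations(x=x, v=eps**2, dt=dt)
        out.append((obs, {"states": states, "y_avg": y_avg, "y_nodes": y_nodes}))
    return out
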