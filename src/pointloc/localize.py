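"""Spot localization with pointwise precision estimates.

Fits Gaussian spot models to single-spot ROIs under the EMCCD count
likelihood, either by maximum likelihood (MLE) or maximum a posteriori (MAP)
estimation, and estimates the localization precision of each fit two ways:

* Laplace approximation: the posterior near its mode is approximated by a
  Gaussian with covariance equal to the inverse Hessian of the negative log
  posterior; the position s.d.s are read off the marginal variances.
* CRLB: the Rieger-Stallinga closed-form approximation to the Cramer-Rao
  bound for a symmetric Gaussian spot on a constant background, with a factor
  2 for EMCCD excess noise.

MAP fitting reparameterizes the width as ``sigma = sigma0 (1 + dsigma)`` with
``dsigma > 0`` structural, so fitted widths can never drop below the
diffraction-limited width ``sigma0``; an exponential prior (mean 1 symmetric,
mean 1/2 per principal width asymmetric) is placed on the excess width
``dsigma``, and a weak normal prior (s.d. ln 30 by default) on the log
background.  Positions and log amplitude carry flat priors.

Internal optimizer coordinates are: position in pixels, then ln b, ln N, and
ln sigma (MLE) or ln dsigma (MAP); for the asymmetric model two width
coordinates plus the rotation angle.  Prior densities are defined on
(dsigma, ln b), and the ln-dsigma change of variables contributes its
log-Jacobian to the internal objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .emccd import CameraModel, log_pcount
from .spotmodel import RoiGeometry, SpotParams, pixel_intensities

__all__ = [
    "PriorConfig",
    "SpotFit",
    "neg_log_posterior",
    "fit_spot",
    "laplace_precision",
    "crlb_precision",
    "filter_fits",
    "conditional_rmse",
    "numeric_hessian",
    "localize_frames",
]


@dataclass
class PriorConfig:
    """Priors for MAP localization.

    ``sigma0`` is the diffraction-limited spot width in nm.  The excess-width
    prior is exponential with mean ``excess_width_mean`` (1 for the symmetric
    model; 1/2 per principal width for the asymmetric one).  The background
    prior is normal in ln b with the given centre and s.d. (default ln 30).
    Position and amplitude priors are flat.
    """

    sigma0: float
    log_background_center: float = 0.0
    log_background_sd: float = math.log(30.0)
    excess_width_mean: float = 1.0
    excess_width_mean_asym: float = 0.5

    def __post_init__(self) -> None:
        if not (self.sigma0 > 0 and self.log_background_sd > 0):
            raise ValueError("sigma0 and log_background_sd must be > 0")
        if not (self.excess_width_mean > 0 and self.excess_width_mean_asym > 0):
            raise ValueError("excess-width prior means must be > 0")


@dataclass
class SpotFit:
    """Result of a single-spot fit.  Lengths in nm unless suffixed ``_px``."""

    params: SpotParams | None
    theta_internal: np.ndarray
    objective: Callable[[np.ndarray], float] = field(repr=False)
    geometry: RoiGeometry = field(repr=False, default=None)
    mode: str = "map"
    model: str = "symmetric"
    converged: bool = False
    loglik_at_max: float = np.nan
    delta_sigma: np.ndarray | None = None
    posterior_cov: np.ndarray | None = None
    precision_x: float = np.nan
    precision_y: float = np.nan
    crlb_sd: float = np.nan
    filter_flags: dict = field(default_factory=dict)
    retained: bool = False

    @property
    def mu_px(self) -> np.ndarray:
        """Fitted position in ROI-local pixel coordinates."""
        a = self.geometry.pixel_size
        return np.array(
            [
                self.params.mu_x / a - self.geometry.origin_x,
                self.params.mu_y / a - self.geometry.origin_y,
            ]
        )


def _unpack(theta, mode, model, sigma0_px):
    """Internal coordinates -> (mu_x_px, mu_y_px, b, N, s1_px, s2_px, phi)."""
    mx, my = theta[0], theta[1]
    b = math.exp(min(theta[2], 50.0))
    N = math.exp(min(theta[3], 50.0))
    if model == "symmetric":
        w = min(theta[4], 50.0)
        if mode == "map":
            s1 = s2 = sigma0_px * (1.0 + math.exp(w))
        else:
            s1 = s2 = math.exp(w)
        phi = 0.0
    else:
        w1, w2 = min(theta[4], 50.0), min(theta[5], 50.0)
        if mode == "map":
            s1 = sigma0_px * (1.0 + math.exp(w1))
            s2 = sigma0_px * (1.0 + math.exp(w2))
        else:
            s1, s2 = math.exp(w1), math.exp(w2)
        phi = theta[6]
    return mx, my, b, N, s1, s2, phi


def neg_log_posterior(
    theta_internal,
    roi,
    cam: CameraModel,
    priors: PriorConfig | None = None,
    mode: str = "map",
    model: str = "symmetric",
    geometry: RoiGeometry | None = None,
) -> float:
    """Negative log posterior (or likelihood, if ``priors is None``/MLE).

    ``roi`` holds raw counts; the camera offset is subtracted internally.
    Finite on the interior of the domain; the prior terms include the
    change-of-variables Jacobian of the internal parameterization.
    """
    roi = np.asarray(roi, dtype=float)
    if not np.all(np.isfinite(roi)):
        raise ValueError("ROI contains non-finite counts")
    if geometry is None:
        geometry = RoiGeometry(
            width=roi.shape[1], height=roi.shape[0], pixel_size=cam.pixel_size
        )
    if mode == "map" and priors is None:
        raise ValueError("MAP mode requires a PriorConfig")
    sigma0_px = priors.sigma0 / cam.pixel_size if priors is not None else None

    theta = np.asarray(theta_internal, dtype=float)
    mx, my, b, N, s1, s2, phi = _unpack(theta, mode, model, sigma0_px)
    a = geometry.pixel_size
    p = SpotParams(
        mu_x=(mx + geometry.origin_x) * a,
        mu_y=(my + geometry.origin_y) * a,
        b=b,
        N=N,
        sigma1=s1 * a,
        sigma2=s2 * a,
        phi=phi,
    )
    E = pixel_intensities(p, geometry)
    nll = -float(np.sum(log_pcount(roi - cam.offset, E, cam)))

    if mode == "map":
        # exponential prior on dsigma, density transformed to ln dsigma
        m = (
            priors.excess_width_mean
            if model == "symmetric"
            else priors.excess_width_mean_asym
        )
        widths = theta[4:5] if model == "symmetric" else theta[4:6]
        for w in widths:
            dsig = math.exp(min(w, 50.0))
            nll += dsig / m + math.log(m) - w
        # normal prior on ln b
        z = (theta[2] - priors.log_background_center) / priors.log_background_sd
        nll += 0.5 * z * z
    return nll


def _initial_theta(roi, cam, mode, model, priors, init, geometry):
    h, w = roi.shape
    if init is None:
        mx, my = w / 2.0, h / 2.0
    else:
        mx, my = float(init[0]), float(init[1])
    border = np.concatenate([roi[0], roi[-1], roi[1:-1, 0], roi[1:-1, -1]])
    b0 = max((np.median(border) - cam.offset) / cam.gain, 0.05)
    N0 = max((roi.sum() - cam.offset * roi.size) / cam.gain - b0 * roi.size, 10.0)
    theta = [mx, my, math.log(b0), math.log(N0)]
    if mode == "map":
        w0 = math.log(0.5)
        theta += [w0] if model == "symmetric" else [w0, w0, 0.0]
    else:
        s0_px = (
            priors.sigma0 / cam.pixel_size if priors is not None else 100.0 / cam.pixel_size
        )
        w0 = math.log(1.2 * s0_px)
        theta += [w0] if model == "symmetric" else [w0, w0, 0.0]
    return np.array(theta)


def fit_spot(
    roi,
    cam: CameraModel,
    mode: str = "map",
    model: str = "symmetric",
    priors: PriorConfig | None = None,
    init=None,
    geometry: RoiGeometry | None = None,
    compute_precision: bool = True,
) -> SpotFit:
    """Quasi-Newton fit of a single spot in an ROI of raw counts.

    ``init`` is the seed position in ROI-local pixel coordinates (defaults to
    the ROI centre).  Optimizer failure is reported via ``converged=False``,
    never raised.
    """
    roi = np.asarray(roi, dtype=float)
    if geometry is None:
        geometry = RoiGeometry(
            width=roi.shape[1], height=roi.shape[0], pixel_size=cam.pixel_size
        )
    obj = lambda th: neg_log_posterior(th, roi, cam, priors, mode, model, geometry)
    theta0 = _initial_theta(roi, cam, mode, model, priors, init, geometry)
    try:
        res = minimize(
            obj,
            theta0,
            method="BFGS",
            jac="2-point",
            options={"gtol": 3e-4, "maxiter": 300, "finite_diff_rel_step": 1e-6},
        )
        # BFGS with finite-difference gradients may stop on "precision loss"
        # with the gradient already far below any meaningful scale; accept
        # those as converged.
        grad_ok = np.linalg.norm(np.atleast_1d(res.jac)) < 0.05
        theta = res.x
        ok = (bool(res.success) or grad_ok) and np.all(np.isfinite(res.x))
        fval = float(res.fun)
    except (ValueError, FloatingPointError):
        theta, ok, fval = theta0, False, np.nan

    sigma0_px = priors.sigma0 / cam.pixel_size if priors is not None else None
    a = geometry.pixel_size
    mx, my, b, N, s1, s2, phi = _unpack(theta, mode, model, sigma0_px)
    params = SpotParams(
        mu_x=(mx + geometry.origin_x) * a,
        mu_y=(my + geometry.origin_y) * a,
        b=b,
        N=N,
        sigma1=s1 * a,
        sigma2=s2 * a,
        phi=phi,
    )
    dsig = None
    if priors is not None:
        dsig = np.array([s * a / priors.sigma0 - 1.0 for s in (s1, s2)])
        if model == "symmetric":
            dsig = dsig[:1]
    fit = SpotFit(
        params=params,
        theta_internal=theta,
        objective=obj,
        geometry=geometry,
        mode=mode,
        model=model,
        converged=ok,
        loglik_at_max=-fval,
        delta_sigma=dsig,
    )
    if ok and model == "symmetric":
        fit.crlb_sd = crlb_precision(params, cam)
    if ok and compute_precision:
        laplace_precision(fit)
    return fit


def numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray, step: float = 1e-4):
    """Central finite-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    n = x.size
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def laplace_precision(fit, step: float = 1e-4):
    """Posterior s.d. of each parameter from the inverse Hessian at the optimum.

    Returns the per-parameter s.d. array (position entries converted to nm)
    and stores the covariance and position precisions on the fit.  A
    non-positive-definite Hessian flags the fit (``hessian_pd`` filter flag)
    and yields no s.d.
    """
    H = numeric_hessian(fit.objective, fit.theta_internal, step=step)
    try:
        np.linalg.cholesky(H)
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        fit.filter_flags["hessian_pd"] = False
        fit.posterior_cov = None
        return None
    fit.filter_flags["hessian_pd"] = True
    fit.posterior_cov = cov
    a = fit.geometry.pixel_size if fit.geometry is not None else 1.0
    sds = np.sqrt(np.diag(cov))
    sds = sds.copy()
    sds[0] *= a
    sds[1] *= a
    fit.precision_x = float(sds[0])
    fit.precision_y = float(sds[1])
    return sds


def crlb_precision(p: SpotParams, cam: CameraModel) -> float:
    """Rieger-Stallinga CRLB approximation for a symmetric Gaussian spot (nm).

    Uses the effective width ``sigma_a^2 = sigma^2 + a^2/12``, the background
    ratio ``tau = 2 pi sigma_a^2 b / (N a^2)``, and an overall factor 2 for
    EMCCD excess noise.
    """
    if not p.is_symmetric:
        raise ValueError("CRLB formula requires the symmetric spot model")
    a = cam.pixel_size
    sigma_a2 = p.sigma1**2 + a**2 / 12.0
    tau = 2.0 * math.pi * sigma_a2 * p.b / (p.N * a**2)
    var = 2.0 * (sigma_a2 / p.N) * (
        1.0 + 4.0 * tau + math.sqrt(2.0 * tau / (1.0 + 4.0 * tau)) if tau > 0 else 1.0
    )
    return math.sqrt(var)


# post-fit retention criteria, in pixels
MAX_DISPLACEMENT_PX = 4.0
MAX_UNCERTAINTY_PX = 16.0
MAX_WIDTH_PX = 9.0


def filter_fits(fits, seeds):
    """Apply the four retention criteria; returns (retained fits, counts).

    Criteria: the fit converged; its position is at most 4 px from the seed
    (ground truth when available, else the ROI seed); its estimated position
    uncertainty is below 16 px; its spot width is below 9 px.  Per-criterion
    flags are stored on each fit.
    """
    seeds = np.asarray(seeds, dtype=float)
    retained = []
    counts = {"converged": 0, "displacement": 0, "uncertainty": 0, "width": 0}
    for fit, seed in zip(fits, seeds):
        a = fit.geometry.pixel_size
        flags = fit.filter_flags
        flags["converged"] = bool(fit.converged)
        if fit.converged:
            d = float(np.hypot(*(fit.mu_px - seed)))
            flags["displacement"] = d <= MAX_DISPLACEMENT_PX
            prec = max(fit.precision_x, fit.precision_y)
            flags["uncertainty"] = np.isfinite(prec) and prec / a < MAX_UNCERTAINTY_PX
            flags["width"] = max(fit.params.sigma1, fit.params.sigma2) / a < MAX_WIDTH_PX
        else:
            flags["displacement"] = flags["uncertainty"] = flags["width"] = False
        for k in counts:
            counts[k] += flags[k]
        fit.retained = all(flags[k] for k in counts)
        if fit.retained:
            retained.append(fit)
    return retained, counts


def conditional_rmse(errors, est_sd, bin_width: float = 7.5, min_count: int = 300):
    """Conditional-consistency ratios RMS(true error)/mean(estimated s.d.).

    Bins points by estimated precision (nm); bins with fewer than
    ``min_count`` points are omitted.  Returns a DataFrame with columns
    ``bin_left, bin_right, n, ratio``.
    """
    errors = np.asarray(errors, dtype=float)
    est_sd = np.asarray(est_sd, dtype=float)
    if errors.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "n", "ratio"])
    idx = np.floor(est_sd / bin_width).astype(int)
    rows = []
    for i in np.unique(idx):
        sel = idx == i
        n = int(sel.sum())
        if n < min_count:
            continue
        rows.append(
            {
                "bin_left": i * bin_width,
                "bin_right": (i + 1) * bin_width,
                "n": n,
                "ratio": float(
                    np.sqrt(np.mean(errors[sel] ** 2)) / np.mean(est_sd[sel])
                ),
            }
        )
    return pd.DataFrame(rows, columns=["bin_left", "bin_right", "n", "ratio"])


_LOC_COLUMNS = [
    "frame", "x_nm", "y_nm", "sd_x_nm", "sd_y_nm", "N", "b", "sigma_nm",
    "sigma1_nm", "sigma2_nm", "phi", "crlb_nm", "converged", "retained",
    "flag_converged", "flag_displacement", "flag_uncertainty", "flag_width",
]


def localize_frames(
    stack,
    seeds: pd.DataFrame,
    cam: CameraModel,
    mode: str = "map",
    model: str = "symmetric",
    priors: PriorConfig | None = None,
    roi_size: int = 9,
):
    """Localize one spot per seed row (columns ``frame, x_px, y_px``).

    Extracts a ``roi_size`` x ``roi_size`` ROI around each seed pixel, fits,
    estimates precision, applies the retention filter against the seed, and
    returns (localization table, list of SpotFit).  Coordinates in the table
    are absolute nm in the stack's pixel frame.
    """
    stack = np.asarray(stack, dtype=float)
    half = roi_size // 2
    fits, seed_px = [], []
    for row in seeds.itertuples(index=False):
        f = int(row.frame)
        img = stack[f]
        cx = int(np.clip(np.floor(row.x_px), half, img.shape[1] - half - 1))
        cy = int(np.clip(np.floor(row.y_px), half, img.shape[0] - half - 1))
        geom = RoiGeometry(
            origin_x=cx - half,
            origin_y=cy - half,
            width=roi_size,
            height=roi_size,
            pixel_size=cam.pixel_size,
        )
        roi = img[geom.origin_y : geom.origin_y + roi_size, geom.origin_x : geom.origin_x + roi_size]
        local_seed = (row.x_px - geom.origin_x, row.y_px - geom.origin_y)
        fit = fit_spot(roi, cam, mode, model, priors, init=local_seed, geometry=geom)
        fits.append(fit)
        seed_px.append(local_seed)
    filter_fits(fits, np.asarray(seed_px))

    rows = []
    for (row, fit) in zip(seeds.itertuples(index=False), fits):
        p = fit.params
        rows.append(
            {
                "frame": int(row.frame),
                "x_nm": p.mu_x,
                "y_nm": p.mu_y,
                "sd_x_nm": fit.precision_x,
                "sd_y_nm": fit.precision_y,
                "N": p.N,
                "b": p.b,
                "sigma_nm": p.sigma1 if fit.model == "symmetric" else np.nan,
                "sigma1_nm": p.sigma1,
                "sigma2_nm": p.sigma2,
                "phi": p.phi,
                "crlb_nm": fit.crlb_sd,
                "converged": fit.converged,
                "retained": fit.retained,
                "flag_converged": fit.filter_flags.get("converged", False),
                "flag_displacement": fit.filter_flags.get("displacement", False),
                "flag_uncertainty": fit.filter_flags.get("uncertainty", False),
                "flag_width": fit.filter_flags.get("width", False),
            }
        )
    return pd.DataFrame(rows, columns=_LOC_COLUMNS), fits
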