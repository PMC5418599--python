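"""EMCCD camera noise model: high-gain electron multiplication plus readout.

A photoelectron entering the electron-multiplication (EM) register produces an
approximately exponentially distributed number of output electrons with mean
equal to the EM gain ``g`` (the high-gain limit of the branching cascade).  For
``n ~ Poisson(E)`` input photons the register output is therefore a
``Gamma(n, g)`` variable, with an atom at zero for ``n = 0``.  The camera adds
zero-mean Gaussian readout noise with s.d. ``readout_sd`` and a constant
``offset``.  The offset-subtracted count ``c`` thus has density

    p(c | E) = e^{-E} N(c; 0, r^2)
             + \\int_0^\\infty f(u; E, g) N(c - u; 0, r^2) du,

where the continuous EM-register branch is

    f(u; E, g) = sqrt(E / (u g)) e^{-u/g - E} I_1(2 sqrt(E u / g)),

``I_1`` the modified Bessel function.  This density underlies both the
localization likelihood and the synthetic-movie sampler, which keeps the two
sides of every simulation/inference test consistent.

Counts are treated as continuous: the readout noise smooths the discrete ADU
grid, and the model is density-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ive

__all__ = ["CameraModel", "log_pcount", "sample_counts"]

# Gauss-Hermite rule used to convolve the EM-register density with the
# readout Gaussian.  The integrand is smooth on the readout scale, so a
# fixed moderate order suffices for all practical (E, gain) combinations.
_GH_ORDER = 33
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(_GH_ORDER)
_LOG_GH_W = np.log(_GH_W)


@dataclass(frozen=True)
class CameraModel:
    """EMCCD calibration.

    Parameters
    ----------
    gain : float
        EM gain, mean output electrons per photoelectron (> 0).
    offset : float
        Constant count offset added by the camera (ADU).
    readout_sd : float
        Gaussian readout noise s.d. in counts (>= 0).
    pixel_size : float
        Back-projected pixel size in nm (> 0).
    """

    gain: float = 50.0
    offset: float = 100.0
    readout_sd: float = 10.0
    pixel_size: float = 80.0

    def __post_init__(self) -> None:
        if not self.gain > 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if self.readout_sd < 0:
            raise ValueError(f"readout_sd must be >= 0, got {self.readout_sd}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")


def _log_em_branch(u, E, gain):
    """log density of the continuous (n >= 1 photon) EM-register branch.

    Vectorized (broadcasts u against E); returns -inf where u <= 0 or E == 0.
    Uses the exponentially scaled Bessel function to stay finite at large
    arguments.
    """
    u_pos = np.maximum(u, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = 2.0 * np.sqrt(E * u_pos / gain)
        # log I_1(x) = log(ive(1, x)) + x
        out = (
            0.5 * (np.log(E) - np.log(u_pos)) - 0.5 * np.log(gain)
            - u_pos / gain
            - E
            + np.log(ive(1, x))
            + x
        )
    return np.where((u > 0) & (E > 0), out, -np.inf)


def log_pcount(c, E, cam: CameraModel):
    """Log density of the offset-subtracted count ``c`` given pixel intensity ``E``.

    ``E`` is the expected number of photons in the pixel.  Broadcasts over
    ``c`` and ``E``.  The Dirac atom at zero EM output (probability
    ``e^{-E}``) is handled analytically as ``e^{-E} N(c; 0, readout_sd^2)``;
    the continuous branch is convolved with the readout Gaussian by
    Gauss-Hermite quadrature.

    Raises
    ------
    ValueError
        If any ``E < 0``, the camera is invalid, or ``readout_sd == 0``
        (the density then contains an unrepresentable point mass).
    """
    c = np.asarray(c, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E < 0):
        raise ValueError("expected photon counts E must be >= 0")
    r = cam.readout_sd
    if r == 0:
        raise ValueError("log_pcount requires readout_sd > 0 (continuous density)")

    c, E = np.broadcast_arrays(c, E)
    # atom: no photoelectrons survive, count is pure readout noise
    log_atom = -E - 0.5 * (c / r) ** 2 - np.log(r) - 0.5 * np.log(2.0 * np.pi)

    # continuous branch convolved with N(0, r^2):
    #   int f(u) N(c-u) du = pi^{-1/2} sum_j w_j f(c - sqrt(2) r x_j)
    u_nodes = c[..., None] - np.sqrt(2.0) * r * _GH_X  # (..., order)
    log_f = _log_em_branch(u_nodes, E[..., None], cam.gain)
    log_terms = _LOG_GH_W + log_f - 0.5 * np.log(np.pi)
    m = np.max(log_terms, axis=-1)
    m_safe = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        log_conv = m_safe + np.log(
            np.sum(np.exp(log_terms - m_safe[..., None]), axis=-1)
        )
    log_conv = np.where(np.isfinite(m), log_conv, -np.inf)

    return np.logaddexp(log_atom, log_conv)


def sample_counts(E_map, cam: CameraModel, rng: np.random.Generator):
    """Sample raw camera counts (offset included) for an expected-photons image.

    Photons per pixel are Poisson(E); each cascade output is Gamma(n, gain);
    Gaussian readout noise and the offset are added.  Consistent with
    :func:`log_pcount` after offset subtraction.
    """
    E_map = np.asarray(E_map, dtype=float)
    if np.any(E_map < 0):
        raise ValueError("expected photon counts must be >= 0")
    n_phot = rng.poisson(E_map)
    electrons = cam.gain * rng.standard_gamma(n_phot)
    counts = electrons + rng.normal(0.0, cam.readout_sd, size=E_map.shape)
    return counts + cam.offset
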