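"""Localization: objective structure, fitting accuracy, Laplace and CRLB
precision estimates, retention filtering, and conditional consistency."""

import math
from types import SimpleNamespace

import numpy as np
import pytest

from pointloc import (
    CameraModel,
    PriorConfig,
    RoiGeometry,
    SpotParams,
    conditional_rmse,
    crlb_precision,
    filter_fits,
    fit_spot,
    laplace_precision,
    neg_log_posterior,
    pixel_intensities,
    sample_counts,
)
from pointloc.localize import numeric_hessian
from tests.conftest import SIGMA0


def _spot_roi(cam, rng, N=600.0, b=1.0, sigma=None, mu_off=(0.0, 0.0)):
    sigma = sigma or SIGMA0 * 1.05
    g = RoiGeometry(width=9, height=9, pixel_size=cam.pixel_size)
    p = SpotParams(
        mu_x=4.5 * cam.pixel_size + mu_off[0],
        mu_y=4.5 * cam.pixel_size + mu_off[1],
        b=b, N=N, sigma=sigma,
    )
    E = pixel_intensities(p, g)
    return sample_counts(E, cam, rng), p, g


def test_map_objective_is_mle_plus_prior_terms(cam, priors, rng):
    roi, _, g = _spot_roi(cam, rng)
    theta = np.array([4.4, 4.6, 0.1, math.log(500.0), math.log(0.4)])
    f_map = neg_log_posterior(theta, roi, cam, priors, "map", "symmetric", g)
    # same physical parameters expressed in MLE coordinates (ln sigma)
    sigma_px = priors.sigma0 / cam.pixel_size * (1.0 + math.exp(theta[4]))
    theta_mle = theta.copy()
    theta_mle[4] = math.log(sigma_px)
    f_mle = neg_log_posterior(theta_mle, roi, cam, None, "mle", "symmetric", g)
    dsig = math.exp(theta[4])
    expected_prior = (
        dsig - theta[4]  # Exp(1) prior on dsigma + ln-Jacobian
        + 0.5 * ((theta[2] - priors.log_background_center) / priors.log_background_sd) ** 2
    )
    assert f_map - f_mle == pytest.approx(expected_prior, abs=1e-12)


def test_objective_is_deterministic(cam, priors, rng):
    roi, _, g = _spot_roi(cam, rng)
    theta = np.array([4.5, 4.5, 0.0, math.log(600.0), math.log(0.5)])
    vals = {neg_log_posterior(theta, roi, cam, priors, "map", "symmetric", g)
            for _ in range(5)}
    assert len(vals) == 1


def test_mle_self_consistency_on_noise_free_image(cam):
    # an "image" equal to the model's expected counts has its MLE at the truth
    g = RoiGeometry(width=9, height=9, pixel_size=cam.pixel_size)
    p = SpotParams(mu_x=4.4 * 80, mu_y=4.6 * 80, b=1.5, N=4000.0, sigma=110.0)
    roi = pixel_intensities(p, g) * cam.gain + cam.offset
    fit = fit_spot(roi, cam, mode="mle", model="symmetric", priors=None)
    assert fit.converged
    assert fit.params.mu_x == pytest.approx(p.mu_x, abs=1e-3 * p.mu_x)
    assert fit.params.mu_y == pytest.approx(p.mu_y, abs=1e-3 * p.mu_y)
    assert fit.params.N == pytest.approx(p.N, rel=1e-3)
    assert fit.params.sigma1 == pytest.approx(p.sigma1, rel=1e-3)


def test_bright_spot_map_position_error_below_10nm(cam, priors, rng):
    errs = []
    for _ in range(8):
        off = rng.uniform(-40, 40, 2)
        roi, p, _ = _spot_roi(cam, rng, N=2000.0, mu_off=tuple(off))
        fit = fit_spot(roi, cam, mode="map", priors=priors)
        assert fit.converged
        errs.append(np.hypot(fit.params.mu_x - p.mu_x, fit.params.mu_y - p.mu_y))
    assert np.median(errs) < 10.0


def test_pure_background_is_not_a_spot(cam, priors, rng):
    roi = sample_counts(np.full((9, 9), 1.0), cam, rng)
    fit = fit_spot(roi, cam, mode="map", priors=priors)
    if fit.converged:
        retained, _ = filter_fits([fit], [(4.5, 4.5)])
        assert retained == [] or fit.precision_x > 0.5 * cam.pixel_size
    else:
        assert not fit.converged


def test_laplace_exact_on_quadratic_objective():
    A = np.array([[4.0, 1.0, 0.0], [1.0, 3.0, 0.5], [0.0, 0.5, 2.0]])
    theta_star = np.array([1.0, -2.0, 0.5])
    obj = lambda th: 0.5 * (th - theta_star) @ A @ (th - theta_star)
    fit = SimpleNamespace(
        objective=obj, theta_internal=theta_star, geometry=None, filter_flags={}
    )
    sds = laplace_precision(fit)
    assert np.allclose(sds, np.sqrt(np.diag(np.linalg.inv(A))), atol=1e-6)


def test_laplace_flags_non_positive_definite_hessian():
    obj = lambda th: -0.5 * float(th @ th)  # maximum, not minimum
    fit = SimpleNamespace(
        objective=obj, theta_internal=np.zeros(2), geometry=None, filter_flags={}
    )
    assert laplace_precision(fit) is None
    assert fit.filter_flags["hessian_pd"] is False


def test_laplace_sd_scales_as_inverse_sqrt_photons(cam, priors):
    # negligible background so the position information is photon-dominated
    g = RoiGeometry(width=9, height=9, pixel_size=cam.pixel_size)
    sds = {}
    for N in (400.0, 1600.0):
        p = SpotParams(mu_x=4.5 * 80, mu_y=4.5 * 80, b=0.01, N=N, sigma=SIGMA0 * 1.3)
        roi = pixel_intensities(p, g) * cam.gain + cam.offset
        fit = fit_spot(roi, cam, mode="map", priors=priors)
        assert fit.converged
        sds[N] = fit.precision_x
    assert sds[400.0] / sds[1600.0] == pytest.approx(2.0, rel=0.05)


def test_crlb_background_free_limit(cam):
    p = SpotParams(mu_x=0, mu_y=0, b=1e-12, N=400.0, sigma=95.85)
    sd = crlb_precision(p, cam)
    sigma_a2 = 95.85**2 + 80.0**2 / 12.0
    assert sd == pytest.approx(math.sqrt(2 * sigma_a2 / 400.0), rel=1e-6)
    assert sd == pytest.approx(6.97, abs=0.01)


def test_crlb_scalings(cam):
    p1 = SpotParams(mu_x=0, mu_y=0, b=1e-12, N=400.0, sigma=100.0)
    p2 = SpotParams(mu_x=0, mu_y=0, b=1e-12, N=800.0, sigma=100.0)
    assert crlb_precision(p1, cam) ** 2 == pytest.approx(
        2 * crlb_precision(p2, cam) ** 2, rel=1e-5
    )
    sds = [
        crlb_precision(SpotParams(mu_x=0, mu_y=0, b=b, N=400.0, sigma=100.0), cam)
        for b in (0.5, 1.0, 2.0, 5.0)
    ]
    assert np.all(np.diff(sds) > 0)


def test_crlb_rejects_asymmetric_model(cam):
    p = SpotParams(mu_x=0, mu_y=0, b=1.0, N=400.0, sigma1=100.0, sigma2=150.0)
    with pytest.raises(ValueError):
        crlb_precision(p, cam)


def _fake_fit(cam, mu_px, sigma_px=1.5, prec_px=0.5, converged=True):
    g = RoiGeometry(width=9, height=9, pixel_size=cam.pixel_size)
    a = cam.pixel_size
    params = SpotParams(
        mu_x=mu_px[0] * a, mu_y=mu_px[1] * a, b=1.0, N=500.0, sigma=sigma_px * a
    )
    return SimpleNamespace(
        params=params, geometry=g, converged=converged,
        precision_x=prec_px * a, precision_y=prec_px * a,
        filter_flags={}, retained=False,
        mu_px=np.array(mu_px, dtype=float),
    )


def test_filter_rejects_displaced_fit(cam):
    fit = _fake_fit(cam, (9.5, 4.5))  # 5 px from the seed
    retained, counts = filter_fits([fit], [(4.5, 4.5)])
    assert retained == []
    assert fit.filter_flags["displacement"] is False


def test_filter_rejects_wide_fit(cam):
    fit = _fake_fit(cam, (4.5, 4.5), sigma_px=9.5)
    retained, _ = filter_fits([fit], [(4.5, 4.5)])
    assert retained == []
    assert fit.filter_flags["width"] is False


def test_filter_retains_good_fit(cam):
    fit = _fake_fit(cam, (5.5, 4.5), sigma_px=1.5, prec_px=0.5)
    retained, counts = filter_fits([fit], [(4.5, 4.5)])
    assert retained == [fit]
    assert all(counts[k] == 1 for k in counts)


def test_conditional_rmse_calibrated(rng):
    n = 100_000
    est = rng.uniform(10.0, 60.0, n)
    errors = rng.standard_normal(n) * est
    table = conditional_rmse(errors, est, bin_width=7.5, min_count=300)
    assert len(table) >= 5
    assert np.all(np.abs(table.ratio - 1.0) < 0.05)


def test_conditional_rmse_single_bin_definition(rng):
    est = np.full(1000, 20.0)
    errors = rng.standard_normal(1000) * 25.0
    table = conditional_rmse(errors, est)
    assert len(table) == 1
    assert table.ratio[0] == pytest.approx(np.sqrt(np.mean(errors**2)) / 20.0, rel=1e-12)
    # homogeneity: doubling the errors doubles every ratio
    table2 = conditional_rmse(2 * errors, est)
    assert table2.ratio[0] == pytest.approx(2 * table.ratio[0], rel=1e-12)


def test_conditional_rmse_empty_input():
    table = conditional_rmse(np.array([]), np.array([]))
    assert len(table) == 0


def test_numeric_hessian_on_known_function():
    f = lambda x: x[0] ** 2 + 3 * x[0] * x[1] + 2.5 * x[1] ** 2
    H = numeric_hessian(f, np.array([0.3, -0.2]))
    assert np.allclose(H, [[2.0, 3.0], [3.0, 5.0]], atol=1e-5)
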