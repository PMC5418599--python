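"""Diffusive HMM: blur constants, variational EM, simplified limits,
classification and position refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from pointloc import (
    DiffusiveHMM,
    Observations,
    blur_constants,
    classify,
    limit_fit,
    misclassification,
    refine_positions,
    synth_hmm_tracks,
    vem_fit,
)
from pointloc.hmm import _band_chain


def _elbo_monotone(trace):
    trace = np.asarray(trace)
    return np.all(np.diff(trace) >= -1e-9 * np.maximum(np.abs(trace[:-1]), 1.0))


# ---------------------------------------------------------------------------
# blur constants


def test_blur_constants_anchors():
    assert blur_constants("continuous") == pytest.approx((1 / 6, 1 / 2, 1 / 12))
    assert blur_constants("delta") == pytest.approx((0.0, 0.0, 0.0))
    R, tau, beta = blur_constants("two-impulse")
    assert (R, tau, beta) == pytest.approx((0.25, 0.5, 0.0))


@settings(max_examples=60, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
def test_random_shutters_obey_blur_bounds(weights):
    w = np.asarray(weights)
    if w.sum() <= 0:
        w = w + 1.0
    R, tau, beta = blur_constants(w)
    assert 0.0 <= R <= 0.25 + 1e-12
    assert 0.0 <= tau <= 1.0
    assert beta >= 0.0


def test_blur_constants_numeric_continuous_limit():
    # dense atom approximation converges to the closed form
    R, tau, beta = blur_constants(np.ones(20001))
    assert R == pytest.approx(1 / 6, abs=1e-4)
    assert tau == pytest.approx(0.5, abs=1e-9)


# ---------------------------------------------------------------------------
# banded Gaussian chain kernel


def test_band_chain_matches_dense_inverse(rng):
    n, bw = 30, 3
    B = np.diag(rng.uniform(10, 20, n))
    for k in range(1, bw + 1):
        v = rng.uniform(-0.5, 0.5, n - k)
        B += np.diag(v, k) + np.diag(v, -k)
    h = rng.standard_normal(n)
    Jb = np.zeros((bw + 1, n))
    for k in range(bw + 1):
        Jb[k, : n - k] = np.diag(B, -k)
    mu, Sb, logdet = _band_chain(Jb, h)
    Sinv = np.linalg.inv(B)
    assert np.allclose(mu, np.linalg.solve(B, h), atol=1e-12)
    for k in range(bw + 1):
        assert np.allclose(Sb[k, : n - k], np.diag(Sinv, -k), atol=1e-12)
    assert logdet == pytest.approx(np.linalg.slogdet(B)[1], rel=1e-12)


# ---------------------------------------------------------------------------
# generator


def test_synth_tracks_moment_check():
    obs, _ = synth_hmm_tracks(
        1, [1.0], [[1.0]], [1.0], dt=0.005, eps_model=30.0,
        n_frames=500_000, n_traj=1, seed=2,
    )[0]
    dx = np.diff(obs.x, axis=0)
    expected = 2 * 1e6 * 0.005 * (2 / 3) + 2 * 900.0
    assert np.mean(dx**2) == pytest.approx(expected, rel=0.01)


def test_synth_tracks_identity_transitions_and_determinism():
    A = np.eye(2)
    t1 = synth_hmm_tracks(2, [0.1, 1.0], A, [0.4, 0.6], dt=0.005,
                          eps_model=20.0, n_frames=200, n_traj=3, seed=9)
    for _, truth in t1:
        assert len(np.unique(truth["states"])) == 1
    t2 = synth_hmm_tracks(2, [0.1, 1.0], A, [0.4, 0.6], dt=0.005,
                          eps_model=20.0, n_frames=200, n_traj=3, seed=9)
    for (o1, _), (o2, _) in zip(t1, t2):
        assert np.array_equal(o1.x, o2.x)


# ---------------------------------------------------------------------------
# variational EM


def test_single_state_msd_collapse():
    rng = np.random.default_rng(3)
    x = np.cumsum(rng.standard_normal((300, 2)) * 100.0, axis=0)
    obs = Observations(x=x, v=np.zeros_like(x), dt=0.005)
    model, post = vem_fit(obs, K=1, tau=0.0, beta=0.0, restarts=1,
                          tol=1e-13, max_iter=10000)
    dx = np.diff(x, axis=0)
    assert model.D[0] == pytest.approx(np.mean(dx**2) / (2 * 0.005) / 1e6, rel=1e-6)


def test_elbo_is_monotone_and_exact_for_single_state():
    obs, _ = synth_hmm_tracks(1, [0.5], [[1.0]], [1.0], dt=0.005,
                              eps_model=(10.0, 50.0), n_frames=250, n_traj=1,
                              seed=4)[0]
    model, post = vem_fit(obs, K=1, restarts=1, tol=1e-13, max_iter=20000)
    assert _elbo_monotone(post.elbo_trace)
    # independent oracle: with a flat prior on the initial position the
    # marginal likelihood is the density of the steps, an MA(1)-type
    # Gaussian with the blur/noise covariances
    sig2 = 2 * model.D[0] * 1e6 * obs.dt
    ll = 0.0
    for ax in range(2):
        dx = np.diff(obs.x[:, ax])
        v = obs.v[:, ax]
        T1 = len(dx)
        S = np.zeros((T1, T1))
        for t in range(T1):
            S[t, t] = sig2 * (1 - 2 * model.R) + v[t] + v[t + 1]
            if t + 1 < T1:
                S[t, t + 1] = S[t + 1, t] = model.R * sig2 - v[t + 1]
        ll += multivariate_normal.logpdf(dx, cov=S)
    assert post.elbo_trace[-1] == pytest.approx(ll, abs=1e-6)


def test_two_state_recovery_and_monotonicity():
    A = np.array([[0.99, 0.01], [0.01, 0.99]])
    tracks = synth_hmm_tracks(2, [0.1, 1.0], A, [0.5, 0.5], dt=0.005,
                              eps_model=(20.0, 60.0), n_frames=1000,
                              n_traj=15, seed=7)
    Ds, As = [], []
    for i, (obs, truth) in enumerate(tracks):
        model, post = vem_fit(obs, K=2, restarts=3, seed=i)
        assert _elbo_monotone(post.elbo_trace)
        assert np.all(np.diff(model.D) > 0)  # states sorted ascending
        Ds.append(model.D)
        As.append(np.diag(model.A))
    med = np.median(Ds, axis=0)
    assert med[0] == pytest.approx(0.1, rel=0.25)
    assert med[1] == pytest.approx(1.0, rel=0.15)
    assert np.median(As, axis=0) == pytest.approx([0.99, 0.99], abs=0.05)


def test_gamma_rows_sum_to_one():
    obs, _ = synth_hmm_tracks(2, [0.1, 1.0], np.array([[0.98, 0.02], [0.02, 0.98]]),
                              [0.5, 0.5], dt=0.005, eps_model=30.0,
                              n_frames=300, n_traj=1, seed=5)[0]
    model, post = vem_fit(obs, K=2, restarts=2, seed=0)
    assert np.allclose(post.gamma.sum(axis=1), 1.0, atol=1e-10)
    assert np.allclose(model.A.sum(axis=1), 1.0, atol=1e-10)


def test_too_short_trajectory_raises():
    obs = Observations(x=np.zeros((3, 2)), v=np.ones((3, 2)), dt=0.005)
    with pytest.raises(ValueError):
        vem_fit(obs, K=2)


# ---------------------------------------------------------------------------
# classification


def test_classify_one_hot_truth_gives_zero_rate():
    gamma = np.zeros((50, 2))
    truth = np.random.default_rng(0).integers(0, 2, 50)
    gamma[np.arange(50), truth] = 1.0
    post = _posterior_with_gamma(gamma)
    assert misclassification(classify(post), truth) == 0.0


def test_classify_uniform_gamma_is_chance(rng):
    gamma = np.full((4000, 2), 0.5)
    gamma[:, 0] += 1e-12  # deterministic argmax
    truth = rng.integers(0, 2, 4000)
    post = _posterior_with_gamma(gamma)
    assert misclassification(classify(post), truth) == pytest.approx(0.5, abs=0.05)


def _posterior_with_gamma(gamma):
    from pointloc.hmm import HMMPosterior

    T = gamma.shape[0]
    z = np.zeros((T, 2))
    return HMMPosterior(gamma=gamma, xi=np.zeros((T - 1, 2, 2)), y_mean=z,
                        y_var=z, y_cov1=z[:-1], refined_mean=z, refined_sd=z)


# ---------------------------------------------------------------------------
# simplified limits


def test_variants_agree_without_blur_or_noise():
    tracks = synth_hmm_tracks(1, [1.0], [[1.0]], [1.0], dt=0.005,
                              shutter="delta", eps_model=1e-6,
                              n_frames=400, n_traj=20, seed=13)
    D_full, D_kal, D_vb = [], [], []
    for i, (obs, _) in enumerate(tracks):
        D_full.append(vem_fit(obs, 1, tau=0.0, beta=0.0, restarts=1)[0].D[0])
        D_kal.append(limit_fit(obs, 1, "kalman", restarts=1)[0].D[0])
        D_vb.append(limit_fit(obs, 1, "vbspt", restarts=1)[0].D[0])
    assert np.mean(D_full) == pytest.approx(np.mean(D_kal), rel=1e-3)
    assert np.mean(D_full) == pytest.approx(np.mean(D_vb), rel=0.02)


def test_kalman_blur_correction_matches_full_fit():
    from pointloc import correct_D

    tracks = synth_hmm_tracks(1, [1.0], [[1.0]], [1.0], dt=0.005,
                              eps_model=20.0, n_frames=500, n_traj=25, seed=19)
    D_full, D_kal = [], []
    for obs, _ in tracks:
        D_full.append(vem_fit(obs, 1, restarts=1)[0].D[0])
        D_kal.append(limit_fit(obs, 1, "kalman", restarts=1)[0].D[0])
    corrected = correct_D(float(np.mean(D_kal)), "kalman", 1 / 6, 0.0, 0.005)
    se = np.std(D_full) / np.sqrt(len(D_full))
    assert corrected == pytest.approx(np.mean(D_full), abs=4 * se + 0.02)


def test_vbspt_elbo_monotone():
    obs, _ = synth_hmm_tracks(2, [0.1, 1.0], np.array([[0.98, 0.02], [0.02, 0.98]]),
                              [0.5, 0.5], dt=0.005, eps_model=30.0,
                              n_frames=400, n_traj=1, seed=6)[0]
    model, post = limit_fit(obs, 2, "vbspt", restarts=2, seed=0)
    assert _elbo_monotone(post.elbo_trace)
    assert np.all(np.diff(model.D) > 0)


# ---------------------------------------------------------------------------
# refinement


def test_static_emitter_refinement_averaging_limit(rng):
    n, eps = 50, 20.0
    x = rng.standard_normal((n, 2)) * eps
    obs = Observations(x=x, v=np.full((n, 2), eps**2), dt=0.01)
    model = DiffusiveHMM(K=1, D=np.array([1e-7]), A=np.array([[1.0]]),
                         pi=np.array([1.0]), dt=0.01, tau=0.5, beta=1 / 12,
                         R=1 / 6)
    mean, sd = refine_positions(obs, model)
    assert sd.mean() == pytest.approx(eps / np.sqrt(n), rel=0.01)
    assert np.allclose(mean, x.mean(axis=0), atol=4 * eps / np.sqrt(n))


def test_zero_error_refinement_returns_measurements():
    obs, _ = synth_hmm_tracks(1, [1.0], [[1.0]], [1.0], dt=0.005,
                              eps_model=1e-9, n_frames=100, n_traj=1, seed=8)[0]
    model, _ = vem_fit(obs, 1, restarts=1)
    mean, sd = refine_positions(obs, model)
    assert np.allclose(mean, obs.x, atol=0.5)


def test_refinement_improves_rmse_most_for_noisy_slow_state():
    tracks = synth_hmm_tracks(
        2, [0.05, 1.0], np.array([[0.99, 0.01], [0.01, 0.99]]), [0.5, 0.5],
        dt=0.005, eps_model=(30.0, 60.0), n_frames=800, n_traj=6, seed=31,
    )
    gains = []
    for i, (obs, truth) in enumerate(tracks):
        model, post = vem_fit(obs, 2, restarts=3, seed=i)
        raw = np.sqrt(np.mean((obs.x - truth["y_avg"]) ** 2))
        ref = np.sqrt(np.mean((post.refined_mean - truth["y_avg"]) ** 2))
        gains.append(1 - ref / raw)
    assert np.mean(gains) > 0.1
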