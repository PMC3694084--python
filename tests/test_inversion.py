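"""EM inversion: conjugate-oracle exactness, ReML, monotone free energy."""

import numpy as np
import pytest

from dcmerp import inversion as inv
from dcmerp import neural as nm
from dcmerp.jacobian import ResponseJacobian
from dcmerp.simulate import generate_dataset


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(7)
    n, N = 150, 4
    G = rng.standard_normal((n, N))
    mu = rng.normal(0, 0.2, N)
    priors = inv.PriorSpec(mu, np.full(N, 0.25))
    theta_true = mu + rng.normal(0, 0.4, N)
    sigma2 = 0.3
    y = G @ theta_true + rng.normal(0, np.sqrt(sigma2), n)
    return G, priors, y, sigma2


def _analytic_posterior(G, priors, y, lam):
    Pi = np.exp(lam)
    S = np.linalg.inv(np.diag(1.0 / priors.variance) + Pi * G.T @ G)
    return S @ (Pi * G.T @ y + priors.mean / priors.variance)


def test_single_e_step_lands_on_conjugate_posterior(linear_problem):
    G, priors, y, sigma2 = linear_problem
    lam = np.array([-np.log(sigma2)])
    prec = inv.PrecisionModel.identity(y.size, lam0=lam[0])
    th1, _, _, _ = inv.e_step(y, priors.mean.copy(), lam, priors, G, prec,
                              h=G @ priors.mean)
    np.testing.assert_allclose(th1, _analytic_posterior(G, priors, y, lam[0]),
                               atol=1e-10)


def test_e_step_no_move_at_perfect_fit(linear_problem):
    G, priors, _, _ = linear_problem
    y = G @ priors.mean
    prec = inv.PrecisionModel.identity(y.size)
    th1, _, _, _ = inv.e_step(y, priors.mean.copy(), np.zeros(1), priors, G,
                              prec, h=y)
    np.testing.assert_allclose(th1, priors.mean, atol=1e-12)


def test_frozen_parameter_never_moves(linear_problem):
    G, priors, y, _ = linear_problem
    var = priors.variance.copy()
    var[2] = 0.0
    frozen_priors = inv.PriorSpec(priors.mean, var)
    prec = inv.PrecisionModel.identity(y.size)
    post = inv.invert_forward(
        y, lambda t: G @ t,
        lambda t, b: ResponseJacobian(matrix=G * (var > 0), steps=np.zeros(4)),
        frozen_priors, prec)
    assert post.mean[2] == frozen_priors.mean[2]


def test_full_inversion_matches_conjugate_closed_form(linear_problem):
    G, priors, y, sigma2 = linear_problem
    lam0 = -np.log(sigma2)
    prec = inv.PrecisionModel.identity(y.size, lam0=lam0)
    opts = inv.InversionOptions(update_hyperparameters=False)
    post = inv.invert_forward(y, lambda t: G @ t,
                              lambda t, b: ResponseJacobian(matrix=G, steps=np.zeros(4)),
                              priors, prec, opts)
    assert post.iterations <= 3
    np.testing.assert_allclose(post.mean, _analytic_posterior(G, priors, y, lam0),
                               atol=1e-6)


def test_reml_recovers_noise_variance():
    rng = np.random.default_rng(11)
    n, N = 2000, 4
    G = rng.standard_normal((n, N))
    priors = inv.PriorSpec(np.zeros(N), np.full(N, 0.25))
    sigma2 = 0.7
    y = G @ rng.normal(0, 0.3, N) + rng.normal(0, np.sqrt(sigma2), n)
    post = inv.invert_forward(y, lambda t: G @ t,
                              lambda t, b: ResponseJacobian(matrix=G, steps=np.zeros(N)),
                              priors, inv.PrecisionModel.identity(n))
    assert np.exp(-post.lam[0]) == pytest.approx(sigma2, rel=0.10)


def test_reml_scale_equivariance():
    """Doubling the residuals quadruples the fitted noise variance."""
    rng = np.random.default_rng(5)
    n, N = 600, 3
    G = rng.standard_normal((n, N))
    priors = inv.PriorSpec(np.zeros(N), np.full(N, 0.25))
    noise = rng.standard_normal(n)
    fitted = []
    for scale in (1.0, 2.0):
        y = scale * noise  # theta stays at the prior mean; residuals scale
        post = inv.invert_forward(y, lambda t: G @ t,
                                  lambda t, b: ResponseJacobian(matrix=G, steps=np.zeros(N)),
                                  priors, inv.PrecisionModel.identity(n))
        fitted.append(np.exp(-post.lam[0]))
    assert fitted[1] / fitted[0] == pytest.approx(4.0, rel=0.05)


def test_zero_residuals_push_lambda_to_clip(linear_problem):
    G, priors, _, _ = linear_problem
    y = G @ priors.mean
    lam = inv.m_step(np.zeros(y.size), G, np.zeros(1),
                     inv.PrecisionModel.identity(y.size), priors,
                     n_inner=40, y=y, h=y, theta=priors.mean.copy())
    assert lam[0] == inv.LAMBDA_CLIP


def test_free_energy_at_perfect_prior_fit(linear_problem):
    G, priors, _, _ = linear_problem
    y = G @ priors.mean
    lam = np.array([1.3])
    prec = inv.PrecisionModel.identity(y.size, lam0=lam[0])
    n = y.size
    w = prec.weights(lam)
    P, logdetP = inv._posterior_precision(G, w, priors)
    expected = (0.5 * np.sum(np.log(w)) - 0.5 * logdetP
                - 0.5 * np.sum(np.log(priors.variance))
                - 0.5 * n * np.log(2 * np.pi))
    F = inv.free_energy(y, y, priors.mean, lam, priors, prec, G)
    assert F == pytest.approx(expected, abs=1e-9)


def test_free_energy_peaks_at_analytic_optimum(linear_problem):
    G, priors, y, sigma2 = linear_problem
    lam = np.array([-np.log(sigma2)])
    prec = inv.PrecisionModel.identity(y.size, lam0=lam[0])
    opt = _analytic_posterior(G, priors, y, lam[0])
    F_opt = inv.free_energy(y, G @ opt, opt, lam, priors, prec, G)
    rng = np.random.default_rng(0)
    for _ in range(5):
        th = opt + rng.normal(0, 0.1, opt.size)
        assert inv.free_energy(y, G @ th, th, lam, priors, prec, G) < F_opt


@pytest.fixture(scope="module")
def tiny_erp_inversion(two_source, leadfield, stim):
    grid = np.arange(0.0, 240.0, 4.0)
    truth = nm.ParameterVector(two_source, np.array([0.3, -0.2, 0.15]))
    ds = generate_dataset(two_source, truth, leadfield, stim, grid,
                          snr=10.0, seed=3)
    return ds, grid, truth


def test_erp_free_energy_trace_monotone(two_source, leadfield, tiny_erp_inversion):
    ds, _, _ = tiny_erp_inversion
    post = inv.invert(ds, two_source, leadfield)
    F = np.asarray(post.free_energy)
    assert np.all(np.diff(F) >= -1e-9)
    assert post.converged


def test_parallel_and_serial_backends_identical_trace(two_source, leadfield,
                                                      tiny_erp_inversion):
    ds, _, _ = tiny_erp_inversion
    post_s = inv.invert(ds, two_source, leadfield,
                        options=inv.InversionOptions(backend="serial"))
    post_p = inv.invert(ds, two_source, leadfield,
                        options=inv.InversionOptions(backend="pool",
                                                     strategy="blockX", workers=3))
    Fs, Fp = np.asarray(post_s.free_energy), np.asarray(post_p.free_energy)
    assert Fs.size == Fp.size
    assert np.abs(Fs - Fp).max() <= 1e-10
    np.testing.assert_allclose(post_s.mean, post_p.mean, atol=1e-12)


def test_posterior_covariance_is_symmetric_psd(two_source, leadfield,
                                               tiny_erp_inversion):
    ds, _, _ = tiny_erp_inversion
    post = inv.invert(ds, two_source, leadfield)
    C = post.covariance
    np.testing.assert_allclose(C, C.T, atol=1e-12)
    assert np.linalg.eigvalsh(C).min() >= -1e-12
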