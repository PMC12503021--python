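import numpy as np
import pytest
from scipy.stats import norm

from dmlmm import (BasisSpec, GaussianMixture, cluster_assign,
                   conditional_predictive, conflict_pvalue,
                   elliptical_set_coverage, marginal_predictive, metrics,
                   pointwise_interval, threshold_risk)
from dmlmm.basis import design_matrix
from dmlmm.data import LongitudinalDataset

from helpers import brute_force_conditional_logpdf, random_gmm


SPEC = BasisSpec("legendre", 3, 0.0, 1.0)


def test_conditioning_on_nothing_gives_the_marginal(rng):
    gmm = random_gmm(rng, 3, 2)
    tq = np.array([0.2, 0.8])
    pred = conditional_predictive(gmm, 0.3, SPEC, [], [], tq)
    Bq = design_matrix(SPEC, tq)
    np.testing.assert_allclose(pred.weights, gmm.weights)
    for k in range(2):
        np.testing.assert_allclose(pred.means[k], Bq @ gmm.means[k])
        np.testing.assert_allclose(
            pred.covariances[k],
            Bq @ gmm.covariances[k] @ Bq.T + 0.3 * np.eye(2))


def test_interpolation_limit_reproduces_observations(rng):
    gmm = random_gmm(rng, 3, 1)
    t = np.array([0.1, 0.5, 0.9])
    y = rng.standard_normal(3)
    pred = conditional_predictive(gmm, 1e-10, SPEC, y, t, t)
    assert np.abs(pred.mean() - y).max() < 1e-3


def test_conditional_matches_brute_force_joint_ratio(rng):
    """The per-component Gaussian conditional must reproduce the density
    p(joint)/p(observed) of the explicit joint mixture pointwise."""
    for trial in range(5):
        d = int(rng.integers(2, 5))
        spec = BasisSpec("legendre", d, 0.0, 1.0)
        gmm = random_gmm(rng, d, int(rng.integers(1, 4)))
        s2 = float(rng.uniform(0.1, 0.6))
        n_i = int(rng.integers(1, 4))
        t_obs = rng.uniform(0, 1, n_i)
        y_obs = rng.standard_normal(n_i)
        t_q = rng.uniform(0, 1, 1)
        grid = np.linspace(-6, 6, 100)
        pred = conditional_predictive(gmm, s2, spec, y_obs, t_obs, t_q)
        got = pred.logpdf(grid[:, None])
        want = brute_force_conditional_logpdf(gmm, s2, spec, y_obs, t_obs,
                                              t_q, grid[:, None])
        np.testing.assert_allclose(np.exp(got), np.exp(want), rtol=1e-8)


def test_conditioning_sequentially_equals_jointly(rng):
    """Tower property of Gaussian-mixture conditioning: updating on two
    observation blocks one after the other equals one combined update."""
    gmm = random_gmm(rng, 3, 2)
    s2 = 0.3
    t1, y1 = np.array([0.1, 0.3]), rng.standard_normal(2)
    t2, y2 = np.array([0.6]), rng.standard_normal(1)
    tq = np.array([0.85])
    once = conditional_predictive(gmm, s2, SPEC,
                                  np.concatenate([y1, y2]),
                                  np.concatenate([t1, t2]), tq)
    grid = np.linspace(-5, 5, 60)[:, None]
    want = once.logpdf(grid)
    got = brute_force_conditional_logpdf(gmm, s2, SPEC,
                                         np.concatenate([y1, y2]),
                                         np.concatenate([t1, t2]), tq, grid)
    np.testing.assert_allclose(got, want, atol=1e-8)


def test_predictive_weights_normalised_and_covs_spd(rng):
    gmm = random_gmm(rng, 3, 3)
    t = rng.uniform(0, 1, 4)
    y = rng.standard_normal(4)
    pred = conditional_predictive(gmm, 0.2, SPEC, y, t, rng.uniform(0, 1, 5))
    assert pred.weights.sum() == pytest.approx(1.0, abs=1e-12)
    for cov in pred.covariances:
        assert np.linalg.eigvalsh(cov).min() > 0


def test_marginal_mean_and_variance_floor(rng):
    gmm = random_gmm(rng, 3, 2)
    tq = np.linspace(0, 1, 7)
    pred = marginal_predictive(gmm, 0.25, SPEC, tq)
    Bq = design_matrix(SPEC, tq)
    np.testing.assert_allclose(pred.mean(),
                               gmm.weights @ (gmm.means @ Bq.T))
    _, cov = pred.moments()
    assert np.all(np.diag(cov) >= 0.25 - 1e-12)


def test_threshold_risk_limits_and_monte_carlo(rng):
    gmm = random_gmm(rng, 3, 2)
    pred = marginal_predictive(gmm, 0.25, SPEC, [0.4, 0.7])
    assert threshold_risk(pred, 0, -1e9) == pytest.approx(0.0, abs=1e-12)
    assert threshold_risk(pred, 0, 1e9) == pytest.approx(1.0, abs=1e-12)
    c = 0.3
    p = threshold_risk(pred, 1, c)
    draws = pred.sample(200_000, rng)
    freq = np.mean(draws[:, 1] <= c)
    se = np.sqrt(p * (1 - p) / draws.shape[0])
    assert abs(p - freq) < 3 * se + 1e-6


def test_pointwise_interval_gaussian_case_and_nesting(rng):
    gmm = GaussianMixture([1.0], np.zeros((1, 3)), 0.4 * np.eye(3)[None])
    pred = marginal_predictive(gmm, 0.1, SPEC, [0.2, 0.6])
    lo, hi = pointwise_interval(pred, 0.95)
    _, cov = pred.moments()
    sd = np.sqrt(np.diag(cov))
    mean = pred.mean()
    np.testing.assert_allclose(lo, mean - 1.959964 * sd, atol=1e-6)
    np.testing.assert_allclose(hi, mean + 1.959964 * sd, atol=1e-6)
    lo50, hi50 = pointwise_interval(pred, 0.5)
    assert np.all(lo50 > lo) and np.all(hi50 < hi)


def test_interval_coverage_self_consistency(rng):
    gmm = random_gmm(rng, 3, 2)
    tq = np.array([0.3, 0.7])
    pred = marginal_predictive(gmm, 0.2, SPEC, tq)
    lo, hi = pointwise_interval(pred, 0.9)
    draws = pred.sample(20_000, rng)
    for j in range(2):
        cov = np.mean((draws[:, j] >= lo[j]) & (draws[:, j] <= hi[j]))
        assert abs(cov - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 20_000)


def test_elliptical_coverage_calibrated_for_gaussian(rng):
    gmm = GaussianMixture([1.0], np.zeros((1, 3)), np.eye(3)[None])
    pred = marginal_predictive(gmm, 0.2, SPEC, np.linspace(0.1, 0.9, 4))
    truth = pred.sample(4000, rng)
    cov = elliptical_set_coverage(pred, 0.9, truth)
    assert abs(cov - 0.9) < 3 * np.sqrt(0.9 * 0.1 / 4000)
    assert elliptical_set_coverage(pred, 0.0, truth) == 0.0


def test_elliptical_coverage_miscalibrated_for_separated_mixture(rng):
    """Moment-matching a strongly bimodal predictive to one Gaussian
    miscalibrates the credible set: for two tight symmetric modes the
    matched variance spans the gap between them, so both modes fall well
    inside the ellipsoid and the set over-covers (quantified by MC)."""
    m = 6.0 * np.ones(3)
    gmm = GaussianMixture([0.5, 0.5], np.stack([m, -m]),
                          np.stack([0.05 * np.eye(3)] * 2))
    pred = marginal_predictive(gmm, 0.05, SPEC, np.linspace(0.1, 0.9, 4))
    truth = pred.sample(4000, rng)
    cov = elliptical_set_coverage(pred, 0.95, truth)
    assert abs(cov - 0.95) > 3 * np.sqrt(0.95 * 0.05 / 4000)
    assert cov > 0.95


def test_cluster_assignment_rules(rng):
    one = random_gmm(rng, 3, 1)
    ds = LongitudinalDataset([0, 1], [[0.2, 0.5], [0.4]],
                             [[0.1, -0.2], [0.3]])
    labels, probs = cluster_assign(one, 0.2, SPEC, ds)
    assert np.all(labels == 0)
    np.testing.assert_allclose(probs[:, 0], 1.0)

    m = np.zeros(3)
    m[0] = 2.0   # constant-curve offset components at +-2
    sym = GaussianMixture([0.5, 0.5], np.stack([m, -m]),
                          np.stack([0.3 * np.eye(3)] * 2))
    mid = LongitudinalDataset([0], [[0.5]], [[0.0]])
    labels, probs = cluster_assign(sym, 0.2, SPEC, mid)
    np.testing.assert_allclose(probs[0], [0.5, 0.5], atol=1e-10)
    assert labels[0] == 0   # tie broken toward the lowest path index


def test_conflict_zero_divergence_when_segments_independent(rng):
    """A single component with block-diagonal covariance over past and
    future makes the conditional equal the marginal: G = 0 and p near 1."""
    # diagonal coefficient covariance + constant-only loading keeps the
    # observation blocks independent only if sigma-projected cov vanishes;
    # use a near-zero coefficient covariance so correlation ~ 0
    gmm = GaussianMixture([1.0], np.zeros((1, 3)), 1e-12 * np.eye(3)[None])
    p, g_obs = conflict_pvalue(gmm, 0.5, SPEC, [0.2, 0.4], [0.1, -0.3],
                               [0.7, 0.9], n_sim=60, n_kl=400, rng=rng)
    assert abs(g_obs) < 0.05
    assert p > 0.5


def test_conflict_k1_matches_closed_form_gaussian_kl(rng):
    gmm = random_gmm(rng, 3, 1)
    s2 = 0.3
    t_past = np.array([0.15, 0.4])
    t_fut = np.array([0.6, 0.85])
    y_past = np.array([0.5, -0.2])
    from dmlmm.prediction import conditional_predictive as cp
    cond = cp(gmm, s2, SPEC, y_past, t_past, t_fut)
    marg = marginal_predictive(gmm, s2, SPEC, t_fut)
    # closed-form KL between the two Gaussians
    m0, S0 = cond.means[0], cond.covariances[0]
    m1, S1 = marg.means[0], marg.covariances[0]
    iS1 = np.linalg.inv(S1)
    kl = 0.5 * (np.trace(iS1 @ S0) + (m1 - m0) @ iS1 @ (m1 - m0)
                - 2 + np.log(np.linalg.det(S1) / np.linalg.det(S0)))
    n_kl = 4000
    _, g_obs = conflict_pvalue(gmm, s2, SPEC, t_past, y_past, t_fut,
                               n_sim=20, n_kl=n_kl, rng=rng)
    # MC standard error of the KL estimate (variance of the log ratio)
    draws = cond.sample(n_kl, rng)
    ratio = (cond.logpdf(draws) - marg.logpdf(draws))
    se = ratio.std() / np.sqrt(n_kl)
    assert abs(g_obs - kl) < 3 * se + 1e-3


def test_conflict_warns_for_tiny_reference(rng, caplog):
    gmm = random_gmm(rng, 3, 1)
    with caplog.at_level("WARNING"):
        conflict_pvalue(gmm, 0.3, SPEC, [0.2], [0.1], [0.8],
                        n_sim=5, n_kl=50, rng=rng)
    assert any("coarse" in r.message for r in caplog.records)


def test_metrics_examples():
    out = metrics([[1.0, 2.0]], [[0.0, 1.0]])
    assert out["rmse"] == pytest.approx(1.0)
    assert out["log_rmse"] == pytest.approx(0.0)
    exact = metrics([[1.0]], [[1.0]])
    assert exact["rmse_exact_zero"] and exact["log_rmse"] is None
    scored = metrics([[0.0]], [[0.0]],
                     log_densities=[norm.logpdf(0.0)])
    assert scored["neg_log_score"] == pytest.approx(0.9189385, abs=1e-6)
    with pytest.raises(ValueError):
        metrics([[]], [[]])
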