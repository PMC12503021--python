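"""Shared test utilities: random model builders and brute-force oracles."""

import numpy as np

from dmlmm import DMFAParameters, GaussianMixture
from dmlmm.basis import design_matrix
from dmlmm.dmfa import mvn_logpdf_chol
from scipy.special import logsumexp


def random_spd(rng, d, scale=1.0):
    A = rng.standard_normal((d, d))
    return scale * (A @ A.T + d * np.eye(d)) / d


def random_gmm(rng, d, K, mean_scale=2.0, cov_scale=0.5):
    w = rng.dirichlet(np.ones(K))
    means = mean_scale * rng.standard_normal((K, d))
    covs = np.stack([random_spd(rng, d, cov_scale) for _ in range(K)])
    return GaussianMixture(w, means, covs)


def random_params(rng, arch, mu_scale=1.0):
    weights, means, loadings, noise = [], [], [], []
    for l in range(arch.n_layers):
        K, Dp, Dc = arch.K[l], arch.D[l], arch.D[l + 1]
        weights.append(rng.dirichlet(np.ones(K) * 3))
        means.append(mu_scale * rng.standard_normal((K, Dp)))
        B = rng.standard_normal((K, Dp, Dc)) * np.tril(np.ones((Dp, Dc)))
        loadings.append(B)
        noise.append(rng.uniform(0.2, 1.0, (K, Dp)))
    return DMFAParameters(arch, weights, means, loadings, noise)


def joint_observation_mixture(gmm, sigma2, spec, t_obs, t_query):
    """Brute-force joint mixture of (y_obs, y_query) induced by the
    coefficient-space mixture: per component the mean is (B_i mu, Bq mu) and
    the covariance the full basis-propagated block matrix plus sigma^2 I on
    the diagonal blocks.  Used as the independent oracle for conditional
    prediction."""
    Bi = design_matrix(spec, t_obs)
    Bq = design_matrix(spec, t_query)
    ni, T = Bi.shape[0], Bq.shape[0]
    stacked = np.vstack([Bi, Bq])
    means = np.stack([stacked @ m for m in gmm.means])
    covs = np.stack([
        stacked @ S @ stacked.T + sigma2 * np.eye(ni + T)
        for S in gmm.covariances])
    return GaussianMixture(gmm.weights, means, covs,
                           path_labels=list(gmm.path_labels))


def brute_force_conditional_logpdf(gmm, sigma2, spec, y_obs, t_obs,
                                   t_query, y_query_grid):
    """log p(y_query | y_obs) evaluated as log p(joint) - log p(obs)."""
    joint = joint_observation_mixture(gmm, sigma2, spec, t_obs, t_query)
    ni = len(np.atleast_1d(y_obs))
    idx = joint.active()
    obs_parts = np.array([
        np.log(joint.weights[k]) + mvn_logpdf_chol(
            np.atleast_1d(y_obs), joint.means[k][:ni],
            joint.covariances[k][:ni, :ni])[0]
        for k in idx])
    log_obs = logsumexp(obs_parts)
    out = np.empty(len(y_query_grid))
    for g, yq in enumerate(y_query_grid):
        xs = np.concatenate([np.atleast_1d(y_obs), np.atleast_1d(yq)])
        joint_parts = np.array([
            np.log(joint.weights[k]) + mvn_logpdf_chol(
                xs, joint.means[k], joint.covariances[k])[0]
            for k in idx])
        out[g] = logsumexp(joint_parts) - log_obs
    return out
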