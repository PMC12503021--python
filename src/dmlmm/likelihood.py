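"""Regression-layer likelihoods and hierarchical prior log-densities.

The observation model is ``y_i = B_i beta_i + eps_i`` with homoscedastic
Gaussian errors.  Marginalising beta_i over the collapsed Gaussian-mixture
prior gives a subject-level mixture likelihood

    p(y_i | eta) = sum_k w_k phi(y_i; B_i mu_k, B_i Sig_k B_i^T + sigma^2 I),

which handles any n_i (including n_i < d and n_i = 1) without special cases.

All Cauchy-type priors are represented hierarchically through inverse-gamma
scale mixtures (the conditionally conjugate forms the variational scheme
relies on):

* sigma^2 | psi ~ IG(1/2, 1/psi), psi ~ IG(1/2, 1/A^2)  (<=> sigma ~ HC(A))
* mu ~ Cauchy(0, c)  as  mu | lam ~ N(0, lam), lam ~ IG(1/2, c^2/2)
* sqrt(delta) ~ HC(c) as  delta | a ~ IG(1/2, 1/a), a ~ IG(1/2, 1/c^2)
* loadings b ~ horseshoe:  b | v_loc, v_glob ~ N(0, v_loc * v_glob) with
  each variance half-Cauchy via its own IG-IG pair.

IG(a, b) is the shape-rate inverse gamma with density
b^a / Gamma(a) x^{-a-1} exp(-b/x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .dmfa import DMFAParameters, GaussianMixture, mvn_logpdf_chol

__all__ = [
    "PriorHyperparameters",
    "subject_marginal_loglik",
    "complete_data_loglik",
    "log_prior_sigma",
    "log_prior_dmfa",
    "ig_logpdf",
]


@dataclass(frozen=True)
class PriorHyperparameters:
    """Scales of the weakly informative hierarchy.

    A : half-Cauchy scale of the error sd (response units).
    c_mu : Cauchy scale of component mean entries.
    c_delta : half-Cauchy scale of layer noise sds.
    horseshoe_scale : half-Cauchy scale of the per-layer global loading scale.
    alpha : symmetric Dirichlet concentration of each layer's weights; small
        values drive the overfitted-mixture pruning mechanism.
    """

    A: float = 5.0
    c_mu: float = 2.5
    c_delta: float = 2.5
    horseshoe_scale: float = 1.0
    alpha: float = 0.5

    def __post_init__(self):
        for name in ("A", "c_mu", "c_delta", "horseshoe_scale", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def ig_logpdf(x, shape, rate):
    """Shape-rate inverse-gamma log-density; domain error off (0, inf)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or shape <= 0 or np.any(np.asarray(rate) <= 0):
        raise ValueError("inverse-gamma log-density needs positive arguments")
    return shape * np.log(rate) - gammaln(shape) - (shape + 1) * np.log(x) - rate / x


def subject_marginal_loglik(y_i, B_i, gmm: GaussianMixture, sigma2) -> float:
    """Marginal mixture log-likelihood of one subject's response vector.

    ``n_i = 0`` returns 0.0 (the log of an empty product), which is what the
    marginal-predictive reduction relies on.
    """
    y_i = np.asarray(y_i, dtype=float).ravel()
    B_i = np.atleast_2d(np.asarray(B_i, dtype=float))
    if y_i.size == 0:
        return 0.0
    if B_i.shape != (y_i.size, gmm.dim):
        raise ValueError(
            f"design shape {B_i.shape} inconsistent with n_i={y_i.size}, d={gmm.dim}"
        )
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    idx = gmm.active()
    parts = np.empty(idx.size)
    eye = sigma2 * np.eye(y_i.size)
    for row, k in enumerate(idx):
        cov = B_i @ gmm.covariances[k] @ B_i.T + eye
        parts[row] = np.log(gmm.weights[k]) + mvn_logpdf_chol(
            y_i, B_i @ gmm.means[k], cov, index=k
        )[0]
    return float(logsumexp(parts))


def complete_data_loglik(y_i, B_i, beta_i, sigma2) -> float:
    """log phi(y_i; B_i beta_i, sigma^2 I)."""
    y_i = np.asarray(y_i, dtype=float).ravel()
    B_i = np.atleast_2d(np.asarray(B_i, dtype=float))
    beta_i = np.asarray(beta_i, dtype=float).ravel()
    if B_i.shape != (y_i.size, beta_i.size):
        raise ValueError("design shape inconsistent with y_i / beta_i")
    r = y_i - B_i @ beta_i
    n = y_i.size
    return float(-0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * (r @ r) / sigma2)


def log_prior_sigma(sigma2, psi, A) -> float:
    """Hierarchical half-Cauchy prior on the error sd:
    log IG(sigma^2; 1/2, 1/psi) + log IG(psi; 1/2, 1/A^2)."""
    if sigma2 <= 0 or psi <= 0 or A <= 0:
        raise ValueError("sigma2, psi and A must be positive")
    return float(ig_logpdf(sigma2, 0.5, 1.0 / psi) + ig_logpdf(psi, 0.5, 1.0 / A**2))


def _dirichlet_logpdf(w, alpha):
    w = np.asarray(w, dtype=float)
    K = w.size
    return float(gammaln(K * alpha) - K * gammaln(alpha) + (alpha - 1) * np.log(w).sum())


def log_prior_dmfa(params: DMFAParameters, aux: dict, hp: PriorHyperparameters) -> float:
    """Joint log-density of all DMFA parameters and shrinkage auxiliaries.

    ``aux`` holds, per layer l (keys are lists over layers):

    * ``lam_mu[l]`` : (K_l, D_{l-1}) Gaussian variances of the Cauchy means
    * ``a_delta[l]`` : (K_l, D_{l-1}) IG auxiliaries of the half-Cauchy noise sds
    * ``v_loc[l]`` : (K_l, D_{l-1}, D_l) local horseshoe variances (free
      entries; ignored above the diagonal)
    * ``nu_loc[l]`` : same shape, their IG auxiliaries
    * ``v_glob[l]``, ``xi_glob[l]`` : scalars, the layer's global horseshoe
      variance and its auxiliary

    Evaluated term by term in the hierarchical representation documented in
    the module docstring.
    """
    arch = params.arch
    total = 0.0
    for l in range(arch.n_layers):
        K_l, Dprev, Dcur = arch.K[l], arch.D[l], arch.D[l + 1]
        free = np.tril_indices(n=Dprev, m=Dcur)   # row >= col
        lam = np.asarray(aux["lam_mu"][l], dtype=float)
        a_d = np.asarray(aux["a_delta"][l], dtype=float)
        v_loc = np.asarray(aux["v_loc"][l], dtype=float)
        nu = np.asarray(aux["nu_loc"][l], dtype=float)
        v_g = float(aux["v_glob"][l])
        xi = float(aux["xi_glob"][l])
        # weights
        total += _dirichlet_logpdf(params.weights[l], hp.alpha)
        # Cauchy means: N(0, lam) x IG(lam; 1/2, c_mu^2/2)
        mu = params.means[l]
        total += np.sum(-0.5 * (np.log(2 * np.pi * lam) + mu**2 / lam))
        total += np.sum(ig_logpdf(lam, 0.5, hp.c_mu**2 / 2.0))
        # half-Cauchy noise sds: IG(delta; 1/2, 1/a) x IG(a; 1/2, 1/c_delta^2)
        dlt = params.noise[l]
        total += np.sum(0.5 * (-np.log(a_d)) - gammaln(0.5)
                        - 1.5 * np.log(dlt) - 1.0 / (a_d * dlt))
        total += np.sum(ig_logpdf(a_d, 0.5, 1.0 / hp.c_delta**2))
        # horseshoe loadings (free entries only)
        b = params.loadings[l][:, free[0], free[1]]
        vl = v_loc[:, free[0], free[1]]
        nl = nu[:, free[0], free[1]]
        total += np.sum(-0.5 * (np.log(2 * np.pi * vl * v_g) + b**2 / (vl * v_g)))
        total += np.sum(ig_logpdf(vl, 0.5, 1.0 / nl) + ig_logpdf(nl, 0.5, 1.0))
        total += float(ig_logpdf(v_g, 0.5, 1.0 / xi)
                       + ig_logpdf(xi, 0.5, 1.0 / hp.horseshoe_scale**2))
    return float(total)
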