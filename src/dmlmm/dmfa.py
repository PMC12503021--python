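"""Deep mixture-of-factor-analyzers (DMFA) prior and Gaussian-mixture algebra.

The DMFA is a layered generative model for a d-dimensional random vector
(here the subject-specific basis coefficients beta_i).  Writing
``z^(0) = beta_i``, each layer l = 1..L draws a component k_l with
probability ``w_k^(l)`` and sets

    z^(l-1) = mu_k^(l) + B_k^(l) z^(l) + eps,   eps ~ N(0, diag(delta_k^(l))),

with ``z^(L) ~ N(0, I)`` at the top.  Dimensions must shrink fast enough for
factor-model identifiability (Anderson-Rubin: D^(l+1) <= (D^(l) - 1)/2).

Marginalising all latents, the prior is an explicit Gaussian mixture whose
components are indexed by "paths" (k_1, ..., k_L) through the layers; the
collapse formulas implemented in :func:`collapse_to_gmm` include the
top-layer N(0, I) contribution (prod_l B)(prod_l B)^T, which the single-layer
special case  B_k B_k^T + delta_k  requires and the sampling oracle confirms.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "DMFAArchitecture",
    "DMFAParameters",
    "GaussianMixture",
    "validate_architecture",
    "sample_random_effects",
    "collapse_to_gmm",
    "gmm_logpdf",
    "gmm_moments",
    "gmm_scalar_cdf",
]

_JITTER = 1e-8


@dataclass(frozen=True)
class DMFAArchitecture:
    """Layer dimensions ``D = (D^(0)=d, ..., D^(L))`` and per-layer component
    counts ``K = (K^(1), ..., K^(L))``; validated at construction."""

    D: tuple
    K: tuple

    def __post_init__(self):
        D = tuple(int(x) for x in self.D)
        K = tuple(int(x) for x in self.K)
        object.__setattr__(self, "D", D)
        object.__setattr__(self, "K", K)
        if len(D) < 2:
            raise ValueError("need at least one layer: D = (d, D1, ...)")
        if len(K) != len(D) - 1:
            raise ValueError("len(K) must equal number of layers len(D) - 1")
        if any(d < 1 for d in D) or any(k < 1 for k in K):
            raise ValueError("dimensions and component counts must be >= 1")
        validate_architecture(self)

    @property
    def n_layers(self) -> int:
        return len(self.K)

    @property
    def d(self) -> int:
        return self.D[0]

    @property
    def n_paths(self) -> int:
        return int(np.prod(self.K))

    def paths(self):
        """All paths (k_1, ..., k_L) in lexicographic order."""
        return list(itertools.product(*[range(k) for k in self.K]))


def validate_architecture(arch: DMFAArchitecture) -> DMFAArchitecture:
    """Enforce the Anderson-Rubin dimension condition on every transition."""
    D = arch.D
    for l in range(len(D) - 1):
        if D[l + 1] > (D[l] - 1) / 2:
            raise ValueError(
                f"architecture violates the Anderson-Rubin condition at layer "
                f"{l + 1}: D({l + 1})={D[l + 1]} > (D({l})-1)/2={(D[l] - 1) / 2}"
            )
    return arch


@dataclass
class DMFAParameters:
    """Per-layer, per-component DMFA parameters.

    ``weights[l]`` is a simplex vector of length K^(l); ``means[l]`` has shape
    (K^(l), D^(l-1)); ``loadings[l]`` has shape (K^(l), D^(l-1), D^(l)) with
    zeros above the diagonal; ``noise[l]`` holds the positive diagonals
    delta_k^(l), shape (K^(l), D^(l-1)).
    """

    arch: DMFAArchitecture
    weights: list = field(default_factory=list)
    means: list = field(default_factory=list)
    loadings: list = field(default_factory=list)
    noise: list = field(default_factory=list)

    def __post_init__(self):
        L = self.arch.n_layers
        D, K = self.arch.D, self.arch.K
        if not (len(self.weights) == len(self.means) == len(self.loadings)
                == len(self.noise) == L):
            raise ValueError("need one weights/means/loadings/noise entry per layer")
        for l in range(L):
            w = np.asarray(self.weights[l], dtype=float)
            if w.shape != (K[l],) or abs(w.sum() - 1.0) > 1e-12 or np.any(w < 0):
                raise ValueError(f"layer {l + 1}: weights must be a simplex vector")
            m = np.asarray(self.means[l], dtype=float)
            if m.shape != (K[l], D[l]):
                raise ValueError(f"layer {l + 1}: means must have shape {(K[l], D[l])}")
            B = np.asarray(self.loadings[l], dtype=float)
            if B.shape != (K[l], D[l], D[l + 1]):
                raise ValueError(f"layer {l + 1}: loadings shape {(K[l], D[l], D[l + 1])}")
            tri = np.triu_indices(n=D[l], m=D[l + 1], k=1)
            if np.any(B[:, tri[0], tri[1]] != 0.0):
                raise ValueError(f"layer {l + 1}: loadings must be lower triangular")
            dlt = np.asarray(self.noise[l], dtype=float)
            if dlt.shape != (K[l], D[l]) or np.any(dlt <= 0):
                raise ValueError(f"layer {l + 1}: noise diagonals must be positive")
            self.weights[l], self.means[l] = w, m
            self.loadings[l], self.noise[l] = B, dlt


@dataclass
class GaussianMixture:
    """Collapsed finite Gaussian mixture over DMFA paths.

    ``weights`` sum to one (zero entries allowed after pruning); ``means`` has
    shape (K, d); ``covariances`` shape (K, d, d), each symmetric PD;
    ``path_labels[k]`` records the layer-component tuple of component k.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    path_labels: list = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        K, d = self.means.shape
        if self.weights.shape != (K,) or self.covariances.shape != (K, d, d):
            raise ValueError("inconsistent mixture shapes")
        if abs(self.weights.sum() - 1.0) > 1e-10 or np.any(self.weights < 0):
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if not np.all(np.isfinite(self.covariances)):
            raise ValueError("covariances must be finite")
        sym_gap = np.abs(self.covariances - np.swapaxes(self.covariances, 1, 2)).max()
        if sym_gap > 1e-8 * max(1.0, float(np.abs(self.covariances).max())):
            raise ValueError("covariances must be symmetric")
        self.covariances = 0.5 * (self.covariances + np.swapaxes(self.covariances, 1, 2))
        if self.path_labels is None:
            self.path_labels = [(k,) for k in range(K)]

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def active(self):
        """Indices of components with positive weight."""
        return np.flatnonzero(self.weights > 0)


def _chol_with_jitter(cov, index=None):
    """Cholesky factor with a logged diagonal jitter fallback for
    near-singular components; raises if the jittered matrix still fails."""
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        logger.warning("jittering near-singular covariance (component %s)", index)
        try:
            return np.linalg.cholesky(cov + _JITTER * np.eye(cov.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance of component {index} is not positive definite"
            ) from exc


def mvn_logpdf_chol(x, mean, cov, index=None):
    """Gaussian log-density via Cholesky; ``x`` may be (d,) or (m, d)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    d = mean.size
    Lc = _chol_with_jitter(cov, index)
    sol = np.linalg.solve(Lc, (x - mean).T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(Lc)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def gmm_component_logpdfs(gmm: GaussianMixture, x):
    """log w_k + log phi(x; mu_k, Sigma_k) for active components.

    Returns (active indices, array of shape (n_active, m))."""
    idx = gmm.active()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    out = np.empty((idx.size, x.shape[0]))
    for row, k in enumerate(idx):
        out[row] = np.log(gmm.weights[k]) + mvn_logpdf_chol(
            x, gmm.means[k], gmm.covariances[k], index=k
        )
    return idx, out


def gmm_logpdf(gmm: GaussianMixture, x):
    """Mixture log-density at ``x`` ((d,) or (m, d)); zero-weight components
    are skipped; evaluation is per-component Cholesky + log-sum-exp."""
    scalar = np.asarray(x).ndim == 1
    _, comp = gmm_component_logpdfs(gmm, x)
    out = logsumexp(comp, axis=0)
    return float(out[0]) if scalar else out


def gmm_moments(gmm: GaussianMixture):
    """Exact mean vector and covariance matrix of the mixture."""
    w = gmm.weights
    mean = w @ gmm.means
    second = np.einsum("k,kij->ij", w, gmm.covariances)
    second += np.einsum("k,ki,kj->ij", w, gmm.means, gmm.means)
    return mean, second - np.outer(mean, mean)


def gmm_scalar_cdf(weights, means, variances, threshold):
    """CDF of a univariate Gaussian mixture: sum_k w_k Phi((c - m_k)/s_k)."""
    weights = np.asarray(weights, dtype=float)
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    if np.any(variances <= 0):
        raise ValueError("component variances must be positive")
    return float(weights @ norm.cdf((threshold - means) / np.sqrt(variances)))


def gmm_sample(gmm: GaussianMixture, n, rng):
    """Draw n samples; returns (samples (n, d), component indices)."""
    rng = np.random.default_rng(rng)
    comp = rng.choice(gmm.n_components, size=n, p=gmm.weights)
    out = np.empty((n, gmm.dim))
    for k in np.unique(comp):
        m = comp == k
        Lc = _chol_with_jitter(gmm.covariances[k], k)
        out[m] = gmm.means[k] + rng.standard_normal((m.sum(), gmm.dim)) @ Lc.T
    return out, comp


def sample_random_effects(params: DMFAParameters, n, rng):
    """Ancestral samples from the DMFA prior.

    Draws ``z^(L) ~ N(0, I)``, then for l = L..1 picks component k_l with
    probability w^(l) and applies the affine-plus-noise map.  Returns the
    ``(n, d)`` matrix of ``z^(0)`` draws and the ``(n, L)`` path assignments.
    """
    rng = np.random.default_rng(rng)
    arch = params.arch
    L = arch.n_layers
    z = rng.standard_normal((n, arch.D[L]))
    path = np.empty((n, L), dtype=int)
    for l in range(L - 1, -1, -1):
        k = rng.choice(arch.K[l], size=n, p=params.weights[l])
        path[:, l] = k
        mu = params.means[l][k]                     # (n, D_l)
        Bz = np.einsum("nij,nj->ni", params.loadings[l][k], z)
        eps = rng.standard_normal((n, arch.D[l])) * np.sqrt(params.noise[l][k])
        z = mu + Bz + eps
    return z, path


def collapse_to_gmm(params: DMFAParameters) -> GaussianMixture:
    """Marginalise the layered latents into an explicit Gaussian mixture.

    For path k = (k_1, ..., k_L), with P_l = B_{k_1}^(1) ... B_{k_l}^(l):

        w_k  = prod_l w_{k_l}^(l)
        mu_k = mu_{k_1}^(1) + sum_{l=2}^L P_{l-1} mu_{k_l}^(l)
        Sig_k = diag(delta_{k_1}^(1)) + sum_{l=2}^L P_{l-1} diag(delta_{k_l}^(l)) P_{l-1}^T
                + P_L P_L^T

    where the last term is the top-layer N(0, I) variance pushed through all
    loadings.  Components are enumerated lexicographically in the path tuple.
    """
    arch = params.arch
    L = arch.n_layers
    d = arch.d
    paths = arch.paths()
    K = len(paths)
    weights = np.empty(K)
    means = np.empty((K, d))
    covs = np.empty((K, d, d))
    for idx, path in enumerate(paths):
        w = 1.0
        mu = params.means[0][path[0]].copy()
        cov = np.diag(params.noise[0][path[0]].copy())
        prefix = params.loadings[0][path[0]].copy()   # P_1
        w *= params.weights[0][path[0]]
        for l in range(1, L):
            k = path[l]
            w *= params.weights[l][k]
            mu = mu + prefix @ params.means[l][k]
            cov = cov + (prefix * params.noise[l][k]) @ prefix.T
            prefix = prefix @ params.loadings[l][k]   # P_{l+1}
        cov = cov + prefix @ prefix.T                 # top-layer N(0, I)
        weights[idx], means[idx], covs[idx] = w, mu, cov
    weights = weights / weights.sum()
    return GaussianMixture(weights, means, covs, path_labels=paths)
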