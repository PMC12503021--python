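"""Structured mean-field variational inference for the deep mixture of LMMs.

The posterior over all unknowns is approximated by a fully factorised family
chosen so that every coordinate update is available in closed form:

* global factors -- Gaussians for component mean shifts (independent
  entries) and for the free lower-triangular loading entries (full
  covariance per output row); inverse-gamma factors for every
  variance-type parameter (layer noise delta, error variance sigma^2, psi,
  and all Cauchy / horseshoe scale-mixture auxiliaries); a Dirichlet factor
  per layer's mixing weights;
* local factors per subject -- a diagonal Gaussian for the basis
  coefficients beta_i, a full-covariance Gaussian for each layer latent
  z_i^(l), and one categorical responsibility vector per layer.

Per-layer responsibilities (rather than one flat categorical over all
paths) keep the per-iteration cost proportional to sum_l K^(l); they are
exact mean-field factors because, given the latent chain, the layer
indicators are conditionally independent.

Optimisation alternates local coordinate ascent with natural-gradient
steps on the global factors.  For exponential-family factors the natural
gradient step of length rho is the convex combination
(1 - rho) * eta_old + rho * eta_target of natural parameters, where
eta_target is the exact conditionally-conjugate optimum computed from the
minibatch with data statistics rescaled by n / |batch|.  With a full batch
and rho = 1 the loop is exact CAVI and the evidence lower bound is
monotone non-decreasing -- the main internal regression check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, logsumexp, xlogy
from sklearn.cluster import KMeans

from .basis import BasisSpec, design_matrix
from .data import LongitudinalDataset
from .dmfa import (DMFAArchitecture, DMFAParameters, GaussianMixture,
                   collapse_to_gmm)
from .likelihood import PriorHyperparameters

logger = logging.getLogger(__name__)

__all__ = ["VIEngine", "FitReport", "prune_empty_components",
           "select_architecture", "fit_best_init"]

_LOG2PI = np.log(2 * np.pi)


def _ig_entropy(shape, rate):
    shape = np.asarray(shape, dtype=float)
    rate = np.asarray(rate, dtype=float)
    return shape + np.log(rate) + gammaln(shape) - (1 + shape) * digamma(shape)


def _dirichlet_entropy(c):
    c = np.asarray(c, dtype=float)
    c0 = c.sum()
    K = c.size
    logB = gammaln(c).sum() - gammaln(c0)
    return logB + (c0 - K) * digamma(c0) - ((c - 1) * digamma(c)).sum()


@dataclass
class FitReport:
    """Trace and summary of one variational fit."""

    elbo_trace: list = field(default_factory=list)       # (iteration, minibatch ELBO)
    full_elbo_checkpoints: list = field(default_factory=list)  # (iteration, full ELBO)
    gmm: GaussianMixture = None
    sigma2: float = None
    responsibilities: list = None                        # per-layer (n, K_l)
    path_labels: np.ndarray = None                       # per-subject argmax path index
    n_iter: int = 0
    seed: int = None
    elbo_parts: tuple = None                             # (L_DMFA, L_Reg) at the end


def prune_empty_components(gmm: GaussianMixture, path_argmax, threshold=0):
    """Zero the weights of paths no subject claims and rescale the rest.

    A path component is empty iff its argmax-responsibility count is
    ``<= threshold`` (default: no subject has it as argmax).
    """
    counts = np.bincount(np.asarray(path_argmax, dtype=int),
                         minlength=gmm.n_components)
    keep = counts > threshold
    if not keep.any():
        raise ValueError("all components empty; cannot prune")
    w = np.where(keep, gmm.weights, 0.0)
    w = w / w.sum()
    return GaussianMixture(w, gmm.means.copy(), gmm.covariances.copy(),
                           path_labels=list(gmm.path_labels))


class VIEngine:
    """Stateful variational solver for one dataset / architecture pair.

    Parameters are plain arrays; all expectations are with respect to the
    current factors.  The public entry points are :meth:`init_state`,
    :meth:`update_locals`, :meth:`global_step`, :meth:`elbo` and :meth:`fit`.
    """

    def __init__(self, data: LongitudinalDataset, spec: BasisSpec,
                 arch: DMFAArchitecture, hp: PriorHyperparameters = None,
                 seed: int = 0):
        if arch.d != spec.d:
            raise ValueError("architecture input dimension must equal basis d")
        self.data = data
        self.spec = spec
        self.arch = arch
        self.hp = hp or PriorHyperparameters()
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.n = data.n_subjects
        self.d = arch.d
        self.L = arch.n_layers

        # fixed per-subject statistics
        self.B = [design_matrix(spec, t) for t in data.times]
        self.G = np.stack([b.T @ b for b in self.B])                    # (n,d,d)
        self.h = np.stack([b.T @ y for b, y in zip(self.B, data.responses)])
        self.yy = np.array([y @ y for y in data.responses])
        self.ni = data.n_obs.astype(float)
        self.N_tot = float(self.ni.sum())

        # lower-triangular masks and free counts per layer
        self.mask = []
        self.nfree = []
        for l in range(self.L):
            Dp, Dc = arch.D[l], arch.D[l + 1]
            m = np.tril(np.ones((Dp, Dc), dtype=bool))
            self.mask.append(m)
            self.nfree.append(np.minimum(np.arange(Dp) + 1, Dc))

    # ------------------------------------------------------------------ #
    # expectations

    def _Einvdelta(self, l):
        return self.sh_delta[l] / self.ra_delta[l]

    def _Elogdelta(self, l):
        return np.log(self.ra_delta[l]) - digamma(self.sh_delta[l])

    def _Elogw(self, l):
        c = self.dir_c[l]
        return digamma(c) - digamma(c.sum())

    @property
    def _Einvsigma2(self):
        return self.sh_sigma2 / self.ra_sigma2

    @property
    def _Elogsigma2(self):
        return np.log(self.ra_sigma2) - digamma(self.sh_sigma2)

    # ------------------------------------------------------------------ #
    # initialisation

    def init_state(self, n_groups=None):
        """Data-driven, deterministic-given-seed layerwise initialisation.

        Ridge projections of y_i onto B_i seed the beta factors.  Each layer
        is then initialised greedily from the one below: k-means on the
        layer's input variables (the ridge coefficients for layer 1, the
        standardized principal scores of the previous layer otherwise)
        assigns responsibilities; occupied components get the cluster mean,
        principal-direction loadings scaled to the component standard
        deviations (masked lower-triangular) and the residual variance as
        noise; the matching standardized scores seed the latent means -- a
        zero latent-mean start is a mean-field saddle at which loadings can
        never grow.  sigma^2 starts at the ridge residual variance.

        ``n_groups`` sets how many components start occupied per layer (an
        int applies to the first layer with 1 for deeper layers; a tuple
        gives one count per layer; None occupies everything).  Unoccupied
        components start broad and nearly weightless: available to the
        overfitted mixture but expected to starve.  See
        :func:`fit_best_init` for ELBO-based selection of the occupancy.
        """
        arch, n, d = self.arch, self.n, self.d
        ridge = self.G + 1e-3 * np.eye(d)
        self.mbeta = np.linalg.solve(ridge, self.h[..., None])[..., 0]
        resid = np.concatenate(
            [y - b @ m for y, b, m in zip(self.data.responses, self.B, self.mbeta)]
        )
        s2 = max(float(np.mean(resid**2)), 1e-4)
        self.vbeta = np.clip(
            s2 * np.diagonal(np.linalg.inv(ridge), axis1=1, axis2=2), 1e-6, 1e3
        ).copy()

        if n_groups is None:
            groups = tuple(arch.K)
        elif np.isscalar(n_groups):
            groups = (int(n_groups),) + (1,) * (self.L - 1)
        else:
            groups = tuple(int(x) for x in n_groups)
            if len(groups) != self.L:
                raise ValueError("n_groups tuple must have one entry per layer")
        groups = tuple(min(max(g, 1), K) for g, K in zip(groups, arch.K))
        self._init_groups = groups
        if n < arch.n_paths:
            logger.warning("n=%d < K_total=%d: overfitted mixture expected to prune",
                           n, arch.n_paths)

        self.resp = []
        self.mmu, self.vmu, self.ra_lam = [], [], []
        self.mb, self.Cb = [], []
        self.sh_delta, self.ra_delta, self.ra_a = [], [], []
        self.ra_vloc, self.ra_nu = [], []
        self.sh_vglob, self.ra_vglob, self.ra_xi = [], [], []
        self.dir_c = []
        self.mz, self.Sz = [], []

        src = self.mbeta
        for l in range(self.L):
            K, Dp, Dc = arch.K[l], arch.D[l], arch.D[l + 1]
            mask = self.mask[l]
            g = groups[l]
            if g > 1 and n >= g:
                km = KMeans(n_clusters=g, n_init=4,
                            random_state=int(self.rng.integers(2**31 - 1)))
                lab = km.fit_predict(src)
                centers = km.cluster_centers_
            else:
                lab = np.zeros(n, dtype=int)
                centers = src.mean(axis=0, keepdims=True)
                g = 1
            r = np.full((n, K), 0.05 / K)
            r[np.arange(n), lab] += 0.95
            self.resp.append(r)

            # global principal structure: broad fallback for unoccupied
            # components and symmetry breaking scale
            Xg = src - src.mean(axis=0)
            _, svg, Vtg = np.linalg.svd(Xg, full_matrices=False)
            ncg = min(Dc, Vtg.shape[0])
            sdg = np.maximum(svg[:ncg] / np.sqrt(n), 1e-3)
            B0g = np.zeros((Dp, Dc))
            B0g[:, :ncg] = Vtg[:ncg].T * sdg
            B0g *= mask
            d0g = np.maximum(Xg.var(axis=0), 1e-3)
            spread = np.maximum(src.std(axis=0), 1e-3)

            mu0 = np.empty((K, Dp))
            B0 = np.zeros((K, Dp, Dc))
            d0 = np.tile(d0g, (K, 1))
            mz0 = np.zeros((n, Dc))
            for k in range(K):
                mem = lab == k
                if k < g and mem.sum() >= 2:
                    mu0[k] = src[mem].mean(axis=0)
                    X = src[mem] - mu0[k]
                    _, sv, Vt = np.linalg.svd(X, full_matrices=False)
                    ncomp = min(Dc, Vt.shape[0])
                    sd = np.maximum(sv[:ncomp] / np.sqrt(max(mem.sum(), 2)),
                                    1e-3)
                    B0[k, :, :ncomp] = Vt[:ncomp].T * sd
                    B0[k] *= mask
                    mz0[mem, :ncomp] = (X @ Vt[:ncomp].T) / sd
                    resvar = (X**2).mean(axis=0) - (B0[k] ** 2).sum(axis=1)
                    d0[k] = np.maximum(resvar, 1e-3)
                elif k < g:
                    mu0[k] = centers[min(k, centers.shape[0] - 1)]
                    B0[k] = B0g
                else:
                    mu0[k] = (src.mean(axis=0)
                              + 0.25 * self.rng.standard_normal(Dp) * spread)
                    B0[k] = B0g
            self.mmu.append(mu0)
            self.vmu.append(np.full((K, Dp), 0.1))
            self.ra_lam.append(self.hp.c_mu**2 / 2.0
                               + 0.5 * (mu0**2 + self.vmu[l]))
            self.mb.append(B0)
            Cb0 = np.zeros((K, Dp, Dc, Dc))
            for j in range(Dp):
                nf = self.nfree[l][j]
                Cb0[:, j, :nf, :nf] = 0.01 * np.eye(nf)
            self.Cb.append(Cb0)

            Nk = self.resp[l].sum(axis=0)
            sh = 0.5 + 0.5 * Nk[:, None] * np.ones((1, Dp))
            self.sh_delta.append(sh)
            self.ra_delta.append(sh * d0)
            self.ra_a.append(1.0 / self.hp.c_delta**2 + 1.0 / d0)

            self.ra_vloc.append(np.where(mask, 1.0 + 0.5 * B0**2, 1.0))
            self.ra_nu.append(np.full((K, Dp, Dc), 2.0))
            nfree_layer = int(mask.sum()) * K
            self.sh_vglob.append(0.5 + 0.5 * nfree_layer)
            self.ra_vglob.append(float(self.sh_vglob[l]))
            self.ra_xi.append(1.0 / self.hp.horseshoe_scale**2 + 1.0)

            self.dir_c.append(self.hp.alpha + Nk)

            self.mz.append(mz0)
            self.Sz.append(np.tile(np.eye(Dc), (n, 1, 1)))
            src = mz0

        self.sh_sigma2 = 0.5 + 0.5 * self.N_tot
        self.ra_sigma2 = self.sh_sigma2 * s2
        self.ra_psi = 1.0 / self.hp.A**2 + 1.0 / s2     # q(psi) shape fixed at 1
        return self

    # ------------------------------------------------------------------ #
    # layer statistics

    def _out_moments(self, l, S):
        """Mean and marginal variance of the layer-l output variable."""
        if l == 0:
            return self.mbeta[S], self.vbeta[S]
        Sm = self.Sz[l - 1][S]
        return self.mz[l - 1][S], np.diagonal(Sm, axis1=1, axis2=2)

    def _layer_Q(self, l, S):
        """E[(x_j - mu_kj - b_kj^T z)^2] for all subjects in S; also returns
        the mean of B_k z (needed by several updates)."""
        X, Vx = self._out_moments(l, S)
        Z = self.mz[l][S]
        SZ = self.Sz[l][S]
        mb, Cb = self.mb[l], self.Cb[l]
        Bzm = np.einsum("kjc,nc->nkj", mb, Z)
        M = X[:, None, :] - self.mmu[l][None] - Bzm
        quad = (np.einsum("kjc,ncd,kjd->nkj", mb, SZ, mb)
                + np.einsum("kjcd,nc,nd->nkj", Cb, Z, Z)
                + np.einsum("kjcd,ncd->nkj", Cb, SZ))
        Q = M**2 + Vx[:, None, :] + self.vmu[l][None] + quad
        return Q, Bzm

    def _EBtDB(self, l):
        """E[B_k^T diag(1/delta_k) B_k] per component, (K, Dc, Dc)."""
        Einvd = self._Einvdelta(l)
        mb, Cb = self.mb[l], self.Cb[l]
        return (np.einsum("kj,kjc,kjd->kcd", Einvd, mb, mb)
                + np.einsum("kj,kjcd->kcd", Einvd, Cb))

    # ------------------------------------------------------------------ #
    # local updates

    def _update_resp(self, l, S):
        Q, _ = self._layer_Q(l, S)
        logits = self._Elogw(l)[None] - 0.5 * np.sum(
            self._Elogdelta(l)[None] + self._Einvdelta(l)[None] * Q, axis=2
        )
        logits -= logsumexp(logits, axis=1, keepdims=True)
        self.resp[l][S] = np.exp(logits)

    def _update_beta(self, S):
        """Gauss-Seidel sweep over the d coordinates of every q(beta_i)."""
        Einvd = self._Einvdelta(0)           # (K, d)
        r = self.resp[0][S]                  # (m, K)
        _, Bzm = self._layer_Q(0, S)
        target = self.mmu[0][None] + Bzm     # (m, K, d)
        prior_prec = r @ Einvd               # (m, d)
        prior_lin = np.einsum("nk,kj,nkj->nj", r, Einvd, target)
        G = self.G[S]
        h = self.h[S]
        es2 = self._Einvsigma2
        m = self.mbeta[S]
        for j in range(self.d):
            prec = es2 * G[:, j, j] + prior_prec[:, j]
            cross = np.einsum("nd,nd->n", G[:, j, :], m) - G[:, j, j] * m[:, j]
            m[:, j] = (es2 * (h[:, j] - cross) + prior_lin[:, j]) / prec
            self.vbeta[S, j] = 1.0 / prec
        self.mbeta[S] = m

    def _update_z(self, l, S):
        """Exact full-covariance update of the layer-l input latent."""
        arch = self.arch
        Dc = arch.D[l + 1]
        r = self.resp[l][S]
        X, _ = self._out_moments(l, S)
        Einvd = self._Einvdelta(l)
        mb = self.mb[l]
        P = np.einsum("nk,kcd->ncd", r, self._EBtDB(l))
        W = Einvd[None] * (X[:, None, :] - self.mmu[l][None])    # (m, K, Dp)
        lin = np.einsum("nk,nkj,kjc->nc", r, W, mb)
        if l == self.L - 1:
            P = P + np.eye(Dc)[None]
        else:
            rn = self.resp[l + 1][S]
            Einvd_n = self._Einvdelta(l + 1)
            diag = rn @ Einvd_n                                   # (m, Dc)
            P = P + diag[:, :, None] * np.eye(Dc)[None]
            Bzm_next = np.einsum("kjc,nc->nkj", self.mb[l + 1], self.mz[l + 1][S])
            lin = lin + np.einsum("nk,kj,nkj->nj", rn, Einvd_n,
                                  self.mmu[l + 1][None] + Bzm_next)
        Sz = np.linalg.inv(P)
        Sz = 0.5 * (Sz + np.swapaxes(Sz, 1, 2))
        self.Sz[l][S] = Sz
        self.mz[l][S] = np.einsum("ncd,nd->nc", Sz, lin)

    def _local_elbo_contribs(self, S):
        """Per-subject ELBO terms that depend on that subject's local factors."""
        es2, els2 = self._Einvsigma2, self._Elogsigma2
        m, v = self.mbeta[S], self.vbeta[S]
        R = (self.yy[S] - 2 * np.einsum("nd,nd->n", self.h[S], m)
             + np.einsum("nc,ncd,nd->n", m, self.G[S], m)
             + np.einsum("ndd,nd->n", self.G[S], v))
        out = -0.5 * self.ni[S] * (_LOG2PI + els2) - 0.5 * es2 * R
        out = out + 0.5 * np.sum(np.log(2 * np.pi * np.e * v), axis=1)
        for l in range(self.L):
            Q, _ = self._layer_Q(l, S)
            r = self.resp[l][S]
            comp = (self._Elogw(l)[None]
                    - 0.5 * np.sum(self._Elogdelta(l)[None] + _LOG2PI
                                   + self._Einvdelta(l)[None] * Q, axis=2))
            out = out + np.sum(r * comp, axis=1) - np.sum(xlogy(r, r), axis=1)
            Sz = self.Sz[l][S]
            Dc = self.arch.D[l + 1]
            sign, logdet = np.linalg.slogdet(Sz)
            out = out + 0.5 * (Dc * (1 + _LOG2PI) + logdet)
        top = self.L - 1
        out = out - 0.5 * (self.arch.D[-1] * _LOG2PI
                           + np.einsum("ndd->n", self.Sz[top][S])
                           + np.sum(self.mz[top][S] ** 2, axis=1))
        return out

    def update_locals(self, S=None, n_inner=20, tol=1e-8):
        """Block coordinate ascent over all local factors of subjects in S.

        Sweeps (responsibilities, beta, all z layers) until the largest
        per-subject local-ELBO change drops below ``tol`` or the sweep cap is
        reached.  Every block update is the exact conditionally-conjugate
        optimum, so the objective is non-decreasing sweep by sweep.
        """
        S = np.arange(self.n) if S is None else np.asarray(S, dtype=int)
        prev = self._local_elbo_contribs(S)
        for sweep in range(n_inner):
            for l in range(self.L):
                self._update_resp(l, S)
            self._update_beta(S)
            for l in range(self.L):
                self._update_z(l, S)
            cur = self._local_elbo_contribs(S)
            if not np.all(np.isfinite(cur)):
                bad = S[~np.isfinite(cur)][:5]
                raise FloatingPointError(
                    f"non-finite local objective for subjects {list(bad)}"
                )
            if np.max(np.abs(cur - prev)) < tol:
                break
            prev = cur
        return cur

    # ------------------------------------------------------------------ #
    # global natural-gradient step

    @staticmethod
    def _blend_ig(shape_old, rate_old, shape_new, rate_new, rho):
        return ((1 - rho) * shape_old + rho * shape_new,
                (1 - rho) * rate_old + rho * rate_new)

    def global_step(self, S=None, rho=1.0):
        """One natural-gradient step on every global factor.

        For each exponential-family factor the step interpolates natural
        parameters between the current value and the conditionally-conjugate
        target computed from the subjects in ``S`` with data statistics
        rescaled by n/|S|; ``rho = 1`` with a full batch is exact CAVI.
        Factors are refreshed sequentially (means, loadings, noise, then
        auxiliaries) so that each target uses current values of the others.
        """
        S = np.arange(self.n) if S is None else np.asarray(S, dtype=int)
        scale = self.n / S.size
        hp = self.hp

        for l in range(self.L):
            K, Dp, Dc = self.arch.K[l], self.arch.D[l], self.arch.D[l + 1]
            mask = self.mask[l]
            r = self.resp[l][S]
            Nk = scale * r.sum(axis=0)

            # mixing weights
            self.dir_c[l] = (1 - rho) * self.dir_c[l] + rho * (hp.alpha + Nk)

            X, _ = self._out_moments(l, S)
            Z = self.mz[l][S]
            SZ = self.Sz[l][S]
            Einvd = self._Einvdelta(l)
            Bzm = np.einsum("kjc,nc->nkj", self.mb[l], Z)

            # component mean shifts (independent entries)
            prec_old = 1.0 / self.vmu[l]
            pm_old = prec_old * self.mmu[l]
            prec_t = 1.0 / self.ra_lam[l] + Einvd * Nk[:, None]
            lin_t = Einvd * scale * np.einsum("nk,nkj->kj", r,
                                              X[:, None, :] - Bzm)
            prec = (1 - rho) * prec_old + rho * prec_t
            pm = (1 - rho) * pm_old + rho * lin_t
            self.vmu[l] = 1.0 / prec
            self.mmu[l] = pm / prec
            self.ra_lam[l] = ((1 - rho) * self.ra_lam[l]
                              + rho * (hp.c_mu**2 / 2.0
                                       + 0.5 * (self.mmu[l] ** 2 + self.vmu[l])))

            # loading rows (full covariance over the free prefix of each row)
            Ezz = SZ + np.einsum("nc,nd->ncd", Z, Z)
            Ezz_r = scale * np.einsum("nk,ncd->kcd", r, Ezz)          # (K,Dc,Dc)
            T = X[:, None, :] - self.mmu[l][None]
            lin_all = scale * np.einsum("nk,nkj,nc->kjc", r, T, Z)    # (K,Dp,Dc)
            Einvvg = self.sh_vglob[l] / self.ra_vglob[l]
            prior_prec = (1.0 / self.ra_vloc[l]) * Einvvg             # shape-1 IG
            for nf in np.unique(self.nfree[l]):
                js = np.flatnonzero(self.nfree[l] == nf)
                # (K, nj, nf, nf) target precision
                Pt = (Einvd[:, js, None, None] * Ezz_r[:, None, :nf, :nf]
                      + np.einsum("kjf,fg->kjfg", prior_prec[:, js, :nf],
                                  np.eye(nf)))
                lt = Einvd[:, js, None] * lin_all[:, js, :nf]
                Cb_old = self.Cb[l][:, js, :nf, :nf]
                P_old = np.linalg.inv(Cb_old)
                pm_old_r = np.einsum("kjfg,kjg->kjf", P_old,
                                     self.mb[l][:, js, :nf])
                P = (1 - rho) * P_old + rho * Pt
                pm_r = (1 - rho) * pm_old_r + rho * lt
                Cnew = np.linalg.inv(P)
                Cnew = 0.5 * (Cnew + np.swapaxes(Cnew, 2, 3))
                self.Cb[l][:, js, :nf, :nf] = Cnew
                self.mb[l][:, js, :nf] = np.einsum("kjfg,kjg->kjf", Cnew, pm_r)

            # layer noise (recompute Q with the refreshed means/loadings)
            Q, _ = self._layer_Q(l, S)
            sh_t = 0.5 + 0.5 * Nk[:, None] * np.ones((1, Dp))
            Einva = 1.0 / self.ra_a[l]        # q(a) has shape 1
            ra_t = Einva + 0.5 * scale * np.einsum("nk,nkj->kj", r, Q)
            self.sh_delta[l], self.ra_delta[l] = self._blend_ig(
                self.sh_delta[l], self.ra_delta[l], sh_t, ra_t, rho)
            self.ra_a[l] = ((1 - rho) * self.ra_a[l]
                            + rho * (1.0 / hp.c_delta**2 + self._Einvdelta(l)))

            # horseshoe auxiliaries
            Eb2 = self.mb[l] ** 2 + np.diagonal(self.Cb[l], axis1=2, axis2=3)
            Eb2 = np.where(mask[None], Eb2, 0.0)
            Einvvg = self.sh_vglob[l] / self.ra_vglob[l]
            ra_vloc_t = np.where(mask[None],
                                 1.0 / self.ra_nu[l] + 0.5 * Eb2 * Einvvg, 1.0)
            self.ra_vloc[l] = (1 - rho) * self.ra_vloc[l] + rho * ra_vloc_t
            self.ra_nu[l] = ((1 - rho) * self.ra_nu[l]
                             + rho * np.where(mask[None],
                                              1.0 + 1.0 / self.ra_vloc[l], 2.0))
            Einvvl = np.where(mask[None], 1.0 / self.ra_vloc[l], 0.0)
            ra_vg_t = (1.0 / self.ra_xi[l]
                       + 0.5 * float(np.sum(Eb2 * Einvvl)))
            self.ra_vglob[l] = (1 - rho) * self.ra_vglob[l] + rho * ra_vg_t
            self.ra_xi[l] = ((1 - rho) * self.ra_xi[l]
                             + rho * (1.0 / hp.horseshoe_scale**2
                                      + self.sh_vglob[l] / self.ra_vglob[l]))

        # error variance and its auxiliary
        m, v = self.mbeta[S], self.vbeta[S]
        R = (self.yy[S] - 2 * np.einsum("nd,nd->n", self.h[S], m)
             + np.einsum("nc,ncd,nd->n", m, self.G[S], m)
             + np.einsum("ndd,nd->n", self.G[S], v))
        sh_t = 0.5 + 0.5 * scale * self.ni[S].sum()
        ra_t = 1.0 / self.ra_psi + 0.5 * scale * R.sum()
        self.sh_sigma2, self.ra_sigma2 = self._blend_ig(
            self.sh_sigma2, self.ra_sigma2, sh_t, ra_t, rho)
        self.ra_psi = ((1 - rho) * self.ra_psi
                       + rho * (1.0 / hp.A**2 + self._Einvsigma2))

        self._check_domain()

    def _check_domain(self):
        ok = (self.sh_sigma2 > 0 and self.ra_sigma2 > 0 and self.ra_psi > 0)
        for l in range(self.L):
            ok = ok and np.all(self.dir_c[l] > 0) and np.all(self.vmu[l] > 0)
            ok = ok and np.all(self.sh_delta[l] > 0) and np.all(self.ra_delta[l] > 0)
            ok = ok and np.all(self.ra_a[l] > 0) and np.all(self.ra_lam[l] > 0)
        if not ok:
            raise FloatingPointError("variational factor left its domain")

    # ------------------------------------------------------------------ #
    # evidence lower bound

    def elbo(self):
        """Closed-form ELBO on the full data; returns (total, L_DMFA, L_Reg).

        L_Reg collects the regression-layer terms (observation likelihood,
        sigma^2/psi priors, and the entropies of q(sigma^2), q(psi) and the
        q(beta_i)); L_DMFA collects everything else.
        """
        hp = self.hp
        S = np.arange(self.n)
        es2, els2 = self._Einvsigma2, self._Elogsigma2
        m, v = self.mbeta, self.vbeta
        R = (self.yy - 2 * np.einsum("nd,nd->n", self.h, m)
             + np.einsum("nc,ncd,nd->n", m, self.G, m)
             + np.einsum("ndd,nd->n", self.G, v))
        L_reg = float(np.sum(-0.5 * self.ni * (_LOG2PI + els2) - 0.5 * es2 * R))
        # sigma^2 / psi priors and entropies;  q(psi) = IG(1, ra_psi)
        einvpsi = 1.0 / self.ra_psi
        elogpsi = np.log(self.ra_psi) - digamma(1.0)
        L_reg += float(-0.5 * elogpsi - gammaln(0.5) - 1.5 * els2 - einvpsi * es2)
        L_reg += float(0.5 * np.log(1.0 / hp.A**2) - gammaln(0.5)
                       - 1.5 * elogpsi - einvpsi / hp.A**2)
        L_reg += float(_ig_entropy(self.sh_sigma2, self.ra_sigma2)
                       + _ig_entropy(1.0, self.ra_psi))
        L_reg += float(0.5 * np.sum(np.log(2 * np.pi * np.e * v)))

        L_dmfa = 0.0
        for l in range(self.L):
            K, Dp, Dc = self.arch.K[l], self.arch.D[l], self.arch.D[l + 1]
            mask = self.mask[l]
            nf_entries = mask.sum()
            Q, _ = self._layer_Q(l, S)
            r = self.resp[l]
            comp = (self._Elogw(l)[None]
                    - 0.5 * np.sum(self._Elogdelta(l)[None] + _LOG2PI
                                   + self._Einvdelta(l)[None] * Q, axis=2))
            L_dmfa += float(np.sum(r * comp) - np.sum(xlogy(r, r)))
            _, logdet = np.linalg.slogdet(self.Sz[l])
            L_dmfa += float(0.5 * np.sum(Dc * (1 + _LOG2PI) + logdet))
            # Dirichlet prior + entropy
            elw = self._Elogw(l)
            L_dmfa += float(gammaln(K * hp.alpha) - K * gammaln(hp.alpha)
                            + (hp.alpha - 1) * elw.sum())
            L_dmfa += float(_dirichlet_entropy(self.dir_c[l]))
            # means: N(0, lam) prior, IG(1/2, c^2/2) on lam;  q(lam)=IG(1, rate)
            einvlam = 1.0 / self.ra_lam[l]
            eloglam = np.log(self.ra_lam[l]) - digamma(1.0)
            emu2 = self.mmu[l] ** 2 + self.vmu[l]
            L_dmfa += float(np.sum(-0.5 * (_LOG2PI + eloglam + einvlam * emu2)))
            L_dmfa += float(np.sum(0.5 * np.log(hp.c_mu**2 / 2.0) - gammaln(0.5)
                                   - 1.5 * eloglam - (hp.c_mu**2 / 2.0) * einvlam))
            L_dmfa += float(np.sum(0.5 * np.log(2 * np.pi * np.e * self.vmu[l])))
            L_dmfa += float(np.sum(_ig_entropy(1.0, self.ra_lam[l])))
            # noise: IG(1/2, 1/a) prior, IG(1/2, 1/c_delta^2) on a
            einvd = self._Einvdelta(l)
            elogd = self._Elogdelta(l)
            einva = 1.0 / self.ra_a[l]
            eloga = np.log(self.ra_a[l]) - digamma(1.0)
            L_dmfa += float(np.sum(-0.5 * eloga - gammaln(0.5)
                                   - 1.5 * elogd - einva * einvd))
            L_dmfa += float(np.sum(0.5 * np.log(1.0 / hp.c_delta**2) - gammaln(0.5)
                                   - 1.5 * eloga - einva / hp.c_delta**2))
            L_dmfa += float(np.sum(_ig_entropy(self.sh_delta[l], self.ra_delta[l])))
            L_dmfa += float(np.sum(_ig_entropy(1.0, self.ra_a[l])))
            # horseshoe loadings
            Eb2 = self.mb[l] ** 2 + np.diagonal(self.Cb[l], axis1=2, axis2=3)
            einvvl = 1.0 / self.ra_vloc[l]
            elogvl = np.log(self.ra_vloc[l]) - digamma(1.0)
            einvnu = 1.0 / self.ra_nu[l]
            elognu = np.log(self.ra_nu[l]) - digamma(1.0)
            einvvg = self.sh_vglob[l] / self.ra_vglob[l]
            elogvg = np.log(self.ra_vglob[l]) - digamma(self.sh_vglob[l])
            mk = mask[None]
            L_dmfa += float(np.sum(np.where(
                mk, -0.5 * (_LOG2PI + elogvl + elogvg + einvvl * einvvg * Eb2), 0.0)))
            L_dmfa += float(np.sum(np.where(
                mk, -0.5 * elognu - gammaln(0.5) - 1.5 * elogvl - einvnu * einvvl,
                0.0)))
            L_dmfa += float(np.sum(np.where(
                mk, -gammaln(0.5) - 1.5 * elognu - einvnu, 0.0)))
            L_dmfa += float(np.sum(np.where(mk, _ig_entropy(1.0, self.ra_vloc[l]),
                                            0.0)))
            L_dmfa += float(np.sum(np.where(mk, _ig_entropy(1.0, self.ra_nu[l]),
                                            0.0)))
            einvxi = 1.0 / self.ra_xi[l]
            elogxi = np.log(self.ra_xi[l]) - digamma(1.0)
            L_dmfa += float(-0.5 * elogxi - gammaln(0.5)
                            - 1.5 * elogvg - einvxi * einvvg)
            L_dmfa += float(0.5 * np.log(1.0 / hp.horseshoe_scale**2) - gammaln(0.5)
                            - 1.5 * elogxi - einvxi / hp.horseshoe_scale**2)
            L_dmfa += float(_ig_entropy(self.sh_vglob[l], self.ra_vglob[l])
                            + _ig_entropy(1.0, self.ra_xi[l]))
            # loading-row entropies
            for nf in np.unique(self.nfree[l]):
                js = np.flatnonzero(self.nfree[l] == nf)
                _, ld = np.linalg.slogdet(self.Cb[l][:, js, :nf, :nf])
                L_dmfa += float(0.5 * np.sum(nf * (1 + _LOG2PI) + ld))
        # top-layer prior
        top = self.L - 1
        L_dmfa += float(np.sum(-0.5 * (self.arch.D[-1] * _LOG2PI
                                       + np.einsum("ndd->n", self.Sz[top])
                                       + np.sum(self.mz[top] ** 2, axis=1))))
        return L_dmfa + L_reg, L_dmfa, L_reg

    # ------------------------------------------------------------------ #
    # fitting loop and post-processing

    def posterior_mean_parameters(self) -> DMFAParameters:
        """Plug-in point estimate: q-means of weights, means, loadings and
        noise diagonals (IG mean when it exists, else the inverse of the
        mean precision)."""
        weights, means, loadings, noise = [], [], [], []
        for l in range(self.L):
            c = self.dir_c[l]
            weights.append(c / c.sum())
            means.append(self.mmu[l].copy())
            loadings.append(self.mb[l] * self.mask[l])
            sh, ra = self.sh_delta[l], self.ra_delta[l]
            mean_ig = np.where(sh > 1.5, ra / np.maximum(sh - 1.0, 0.5), ra / sh)
            noise.append(mean_ig)
        return DMFAParameters(self.arch, weights, means, loadings, noise)

    @property
    def sigma2_hat(self) -> float:
        return float(self.ra_sigma2 / (self.sh_sigma2 - 1.0))

    def path_responsibilities(self):
        """(n, K_total) products of per-layer responsibilities, path order
        lexicographic (matching collapse_to_gmm)."""
        out = self.resp[0]
        for l in range(1, self.L):
            out = np.einsum("na,nb->nab", out, self.resp[l]).reshape(self.n, -1)
        return out

    def fit(self, n_iter=1000, batch_size=64, step_kappa=0.75, step_tau=10.0,
            n_inner=20, inner_tol=1e-8, full_batch=False, elbo_every=None,
            log_every=50) -> FitReport:
        """Run the stochastic natural-gradient loop and post-process.

        ``full_batch=True`` uses every subject each iteration with unit step
        sizes (exact CAVI); otherwise minibatches of ``batch_size`` are drawn
        without replacement (reshuffled each epoch) with the Robbins-Monro
        schedule rho_m = (m + step_tau)^(-step_kappa).
        """
        report = FitReport(seed=self.seed)
        perm = self.rng.permutation(self.n)
        pos = 0
        bs = self.n if (full_batch or batch_size is None) else min(batch_size, self.n)
        for m in range(1, n_iter + 1):
            if bs >= self.n:
                S = np.arange(self.n)
            else:
                if pos + bs > self.n:
                    perm = self.rng.permutation(self.n)
                    pos = 0
                S = perm[pos:pos + bs]
                pos += bs
            local = self.update_locals(S, n_inner=n_inner, tol=inner_tol)
            rho = 1.0 if full_batch else float((m + step_tau) ** (-step_kappa))
            try:
                self.global_step(S, rho=rho)
            except FloatingPointError as exc:
                raise FloatingPointError(f"iteration {m}: {exc}") from exc
            mb_elbo = float(local.sum() * self.n / S.size)
            report.elbo_trace.append((m, mb_elbo))
            if elbo_every and (m % elbo_every == 0 or m == n_iter):
                report.full_elbo_checkpoints.append((m, self.elbo()[0]))
            if log_every and m % log_every == 0:
                logger.info("iter %d  minibatch-ELBO %.3f  rho %.4f", m, mb_elbo, rho)
        # final full-data local pass, prune, collapse
        self.update_locals(None, n_inner=n_inner, tol=inner_tol)
        params = self.posterior_mean_parameters()
        gmm = collapse_to_gmm(params)
        path_r = self.path_responsibilities()
        path_argmax = np.argmax(path_r, axis=1)
        pruned = prune_empty_components(gmm, path_argmax)
        report.gmm = pruned
        report.sigma2 = self.sigma2_hat
        report.responsibilities = [r.copy() for r in self.resp]
        report.path_labels = path_argmax
        report.n_iter = n_iter
        total, ld, lr = self.elbo()
        report.elbo_parts = (ld, lr)
        report.full_elbo_checkpoints.append((n_iter, total))
        return report


def fit_best_init(data, spec, arch, hp=None, seed=0, candidates=None,
                  select_iters=50, n_iter=1000, **fit_kwargs):
    """Fit after choosing the initial per-layer occupancy by short runs.

    Mean-field coordinate ascent for mixtures is sensitive to how many
    components start occupied: seeding every component splits real clusters
    into stable sub-optima, seeding too few merges them.  Following the
    short-run-ELBO philosophy used for architecture choice, candidate
    occupancies are fitted for ``select_iters`` iterations from the same
    seed and the best full-data-ELBO start is refitted in full.

    The default candidate set is staged to stay affordable: first the
    first-layer count is chosen from 1..K^(1) with deeper layers at one
    occupied component, then each deeper layer's count is chosen in turn
    given the layers already fixed (sum_l K^(l) short runs in total rather
    than prod_l).  ``candidates`` may instead give an explicit list of
    per-layer occupancy tuples.  Returns (engine, report).
    """
    short_kwargs = dict(fit_kwargs)
    short_kwargs["log_every"] = 0

    def short_elbo(groups):
        eng = VIEngine(data, spec, arch, hp=hp, seed=seed)
        eng.init_state(n_groups=groups)
        eng.fit(n_iter=select_iters, **short_kwargs)
        e = eng.elbo()[0]
        logger.info("init occupancy %s: short-run ELBO %.2f", groups, e)
        return e

    L = arch.n_layers
    if candidates is not None:
        candidates = [(int(c),) + (1,) * (L - 1) if np.isscalar(c)
                      else tuple(c) for c in candidates]
        if not candidates:
            raise ValueError("empty candidate list")
        scores = [short_elbo(c) for c in candidates]
        best = candidates[int(np.argmax(scores))]
    else:
        best = [1] * L
        best_e = -np.inf
        for g in range(1, arch.K[0] + 1):
            e = short_elbo(tuple([g] + best[1:]))
            if e > best_e:
                best[0], best_e = g, e
        for l in range(1, L):
            for g in range(2, arch.K[l] + 1):
                trial = list(best)
                trial[l] = g
                e = short_elbo(tuple(trial))
                if e > best_e:
                    best[l], best_e = g, e
        best = tuple(best)
    engine = VIEngine(data, spec, arch, hp=hp, seed=seed)
    engine.init_state(n_groups=best)
    report = engine.fit(n_iter=n_iter, **fit_kwargs)
    return engine, report


def _param_count(arch: DMFAArchitecture) -> int:
    total = 0
    for l in range(arch.n_layers):
        Dp, Dc, K = arch.D[l], arch.D[l + 1], arch.K[l]
        nfree = int(np.tril(np.ones((Dp, Dc))).sum())
        total += K * (2 * Dp + nfree) + K
    return total


def select_architecture(data, spec, candidates, hp=None, seed=0, short_iters=100,
                        **fit_kwargs):
    """Rank candidate architectures by the ELBO of short fits.

    Each candidate is fitted for ``short_iters`` iterations from the same
    seed; candidates are returned sorted by descending full-data ELBO, ties
    broken by fewer parameters, then input order.  Returns a list of
    (architecture, elbo) pairs.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    results = []
    for pos, arch in enumerate(candidates):
        eng = VIEngine(data, spec, arch, hp=hp, seed=seed).init_state()
        eng.fit(n_iter=short_iters, log_every=0, **fit_kwargs)
        results.append((arch, float(eng.elbo()[0]), _param_count(arch), pos))
    results.sort(key=lambda t: (-round(t[1], 9), t[2], t[3]))
    return [(a, e) for a, e, _, _ in results]
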