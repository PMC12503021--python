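"""Scikit-learn style estimator front end.

:class:`DMLMM` wraps the variational engine behind the familiar
``fit / predict / score`` surface.  Long-format input is accepted either as
a :class:`~dmlmm.data.LongitudinalDataset`, a pandas DataFrame with
subject / time / value columns, or an ``(n_obs, 2)`` array of
``(subject, time)`` rows with the responses passed as ``y``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .basis import BasisSpec
from .data import LongitudinalDataset
from .dmfa import DMFAArchitecture
from .likelihood import PriorHyperparameters, subject_marginal_loglik
from .prediction import (cluster_assign, conditional_predictive,
                         conflict_pvalue, marginal_predictive)
from .basis import design_matrix
from .vi import VIEngine, fit_best_init

__all__ = ["DMLMM"]


def _as_dataset(X, y=None, id_col="subject", time_col="time", value_col="value"):
    if isinstance(X, LongitudinalDataset):
        return X
    if isinstance(X, pd.DataFrame):
        if value_col in X.columns and y is None:
            return LongitudinalDataset.from_frame(X, id_col, time_col, value_col)
        df = X[[id_col, time_col]].copy()
        df[value_col] = np.asarray(y, dtype=float)
        return LongitudinalDataset.from_frame(df, id_col, time_col, value_col)
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("array input must have two columns: (subject, time)")
    if y is None:
        raise ValueError("responses y are required with array input")
    df = pd.DataFrame({id_col: X[:, 0], time_col: X[:, 1].astype(float),
                       value_col: np.asarray(y, dtype=float)})
    return LongitudinalDataset.from_frame(df, id_col, time_col, value_col)


class DMLMM(BaseEstimator):
    """Deep mixture of linear mixed models for unbalanced longitudinal data.

    The temporal trend of each subject is ``y_i = B(t_i) beta_i + eps_i``
    with a d-dimensional basis expansion; the subject coefficients beta_i
    carry a deep mixture-of-factor-analyzers prior that collapses to a
    Gaussian mixture over paths, fitted by structured mean-field variational
    inference with natural-gradient stochastic steps.

    Parameters
    ----------
    d : int
        Basis dimension.
    basis : {'legendre', 'bspline_seasonal'}
        Basis family; the seasonal family needs ``period`` and ``n_seasonal``.
    layer_dims : tuple of int
        Latent dimensions (D^(1), ..., D^(L)); must shrink per the
        Anderson-Rubin condition D^(l+1) <= (D^(l)-1)/2 with D^(0) = d.
    layer_components : tuple of int
        Mixture components per layer (K^(1), ..., K^(L)); the collapsed
        prior has prod K^(l) path components (overfitted mixtures prune).
    domain : (float, float), optional
        Basis time domain; defaults to the observed range at fit time.
    A, c_mu, c_delta, horseshoe_scale, alpha : float
        Prior scales (error-sd half-Cauchy, mean Cauchy, noise-sd
        half-Cauchy, loading horseshoe global scale, Dirichlet
        concentration).
    n_iter, batch_size, full_batch, step_kappa, step_tau : optimisation
        Natural-gradient loop controls; ``full_batch=True`` with any
        ``batch_size`` runs exact coordinate ascent with unit steps.
    n_inner, inner_tol : local coordinate-ascent cap and tolerance.
    elbo_every : int, optional
        Record the full-data ELBO every this many iterations.
    random_state : int
        Seed for initialisation and minibatch sampling.

    Attributes
    ----------
    gmm_ : GaussianMixture
        Pruned collapsed prior over basis coefficients.
    sigma2_ : float
        Posterior-mean error variance.
    basis_spec_ : BasisSpec
    labels_ : ndarray
        Training subjects' argmax path labels.
    report_ : FitReport
        ELBO traces and responsibilities.
    """

    def __init__(self, d=10, basis="legendre", layer_dims=(4, 1),
                 layer_components=(6, 3), domain=None, period=None,
                 n_seasonal=None, A=5.0, c_mu=2.5, c_delta=2.5,
                 horseshoe_scale=1.0, alpha=0.5, n_iter=1000, batch_size=64,
                 full_batch=False, step_kappa=0.75, step_tau=10.0, n_inner=20,
                 inner_tol=1e-8, elbo_every=None, init_groups=None,
                 init_select_iters=50, random_state=0):
        self.d = d
        self.basis = basis
        self.layer_dims = layer_dims
        self.layer_components = layer_components
        self.domain = domain
        self.period = period
        self.n_seasonal = n_seasonal
        self.A = A
        self.c_mu = c_mu
        self.c_delta = c_delta
        self.horseshoe_scale = horseshoe_scale
        self.alpha = alpha
        self.n_iter = n_iter
        self.batch_size = batch_size
        self.full_batch = full_batch
        self.step_kappa = step_kappa
        self.step_tau = step_tau
        self.n_inner = n_inner
        self.inner_tol = inner_tol
        self.elbo_every = elbo_every
        self.init_groups = init_groups
        self.init_select_iters = init_select_iters
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _make_spec(self, dataset):
        if self.domain is not None:
            lo, hi = self.domain
        else:
            lo, hi = dataset.time_range
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
        return BasisSpec(self.basis, self.d, float(lo), float(hi),
                         period=self.period, n_seasonal=self.n_seasonal)

    def fit(self, X, y=None):
        """Fit the model on long-format data; returns self."""
        dataset = _as_dataset(X, y)
        spec = self._make_spec(dataset)
        arch = DMFAArchitecture((self.d, *self.layer_dims),
                                tuple(self.layer_components))
        hp = PriorHyperparameters(A=self.A, c_mu=self.c_mu,
                                  c_delta=self.c_delta,
                                  horseshoe_scale=self.horseshoe_scale,
                                  alpha=self.alpha)
        fit_kwargs = dict(batch_size=self.batch_size,
                          full_batch=self.full_batch,
                          step_kappa=self.step_kappa, step_tau=self.step_tau,
                          n_inner=self.n_inner, inner_tol=self.inner_tol,
                          elbo_every=self.elbo_every)
        seed = int(self.random_state or 0)
        if self.init_groups is None:
            engine, report = fit_best_init(
                dataset, spec, arch, hp=hp, seed=seed,
                select_iters=self.init_select_iters, n_iter=self.n_iter,
                **fit_kwargs)
        else:
            engine = VIEngine(dataset, spec, arch, hp=hp, seed=seed)
            engine.init_state(n_groups=int(self.init_groups))
            report = engine.fit(n_iter=self.n_iter, **fit_kwargs)
        self.basis_spec_ = spec
        self.architecture_ = arch
        self.gmm_ = report.gmm
        self.sigma2_ = report.sigma2
        self.report_ = report
        self.elbo_trace_ = report.elbo_trace
        self.labels_ = report.path_labels
        self.n_subjects_ = dataset.n_subjects
        self.training_data_ = {
            sid: (dataset.times[i], dataset.responses[i])
            for i, sid in enumerate(dataset.subject_ids)
        }
        self._engine = engine
        return self

    # ------------------------------------------------------------------ #

    def predict(self, X):
        """Predictive mean at the (subject, time) rows of ``X``.

        Subjects seen during fitting are predicted conditionally on their
        training observations; unseen subjects get the marginal mean.
        """
        check_is_fitted(self, "gmm_")
        if isinstance(X, pd.DataFrame):
            sids = X.iloc[:, 0].to_numpy()
            ts = X.iloc[:, 1].to_numpy(dtype=float)
        else:
            X = np.asarray(X)
            sids, ts = X[:, 0], X[:, 1].astype(float)
        out = np.empty(len(ts))
        for sid in pd.unique(sids):
            rows = np.flatnonzero(sids == sid)
            tq = ts[rows]
            if sid in self.training_data_:
                t_obs, y_obs = self.training_data_[sid]
                pred = conditional_predictive(self.gmm_, self.sigma2_,
                                              self.basis_spec_, y_obs, t_obs, tq)
            else:
                pred = marginal_predictive(self.gmm_, self.sigma2_,
                                           self.basis_spec_, tq)
            out[rows] = pred.mean()
        return out

    def predict_conditional(self, y_obs, t_obs, t_query):
        """Full conditional predictive mixture for one subject."""
        check_is_fitted(self, "gmm_")
        return conditional_predictive(self.gmm_, self.sigma2_,
                                      self.basis_spec_, y_obs, t_obs, t_query)

    def predict_marginal(self, t_query):
        check_is_fitted(self, "gmm_")
        return marginal_predictive(self.gmm_, self.sigma2_,
                                   self.basis_spec_, t_query)

    def score(self, X, y=None):
        """Mean per-subject marginal log-likelihood of new data."""
        check_is_fitted(self, "gmm_")
        dataset = _as_dataset(X, y)
        vals = [
            subject_marginal_loglik(
                dataset.responses[i],
                design_matrix(self.basis_spec_, dataset.times[i]),
                self.gmm_, self.sigma2_)
            for i in range(dataset.n_subjects)
        ]
        return float(np.mean(vals))

    def cluster(self, X=None, y=None):
        """Path labels and posterior path probabilities for subjects."""
        check_is_fitted(self, "gmm_")
        if X is None:
            dataset = LongitudinalDataset(
                list(self.training_data_.keys()),
                [v[0] for v in self.training_data_.values()],
                [v[1] for v in self.training_data_.values()])
        else:
            dataset = _as_dataset(X, y)
        return cluster_assign(self.gmm_, self.sigma2_, self.basis_spec_, dataset)

    def conflict_check(self, y_obs, t_obs, split_index, n_sim=200, n_kl=2000,
                       rng=None):
        """Prior-data-conflict p-value splitting one trajectory at
        ``split_index`` into past (conditioning) and future segments."""
        check_is_fitted(self, "gmm_")
        y_obs = np.asarray(y_obs, dtype=float).ravel()
        t_obs = np.asarray(t_obs, dtype=float).ravel()
        return conflict_pvalue(self.gmm_, self.sigma2_, self.basis_spec_,
                               t_obs[:split_index], y_obs[:split_index],
                               t_obs[split_index:], n_sim=n_sim, n_kl=n_kl,
                               rng=rng)
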