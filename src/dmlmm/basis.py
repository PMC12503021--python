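"""Design matrices B(t): Legendre polynomial and seasonal B-spline bases.

The regression layer of the model is ``y_i = B(t_i) beta_i + eps_i`` with a
known ``n_i x d`` design matrix built by evaluating ``d`` basis functions at
the observation times.  Two families are provided:

* ``legendre`` -- unnormalised Legendre polynomials ``P_0 .. P_{d-1}``
  evaluated on the observation times rescaled affinely to ``[-1, 1]``.
* ``bspline_seasonal`` -- ``n_seasonal`` exactly-periodic cubic B-splines of
  a given period (for seasonal forcing) concatenated with ``n_trend`` cubic
  B-splines on the full domain with equispaced knots (additive trend).

Times outside the stored domain raise rather than extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.interpolate import BSpline

__all__ = ["BasisSpec", "design_matrix"]


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a ``d``-dimensional basis on a fixed time domain.

    For ``kind='bspline_seasonal'`` the first ``n_seasonal`` columns are
    periodic in ``period`` and the remaining ``d - n_seasonal`` columns are
    ordinary cubic B-splines on ``(t_min, t_max)``.
    """

    kind: str  # 'legendre' | 'bspline_seasonal'
    d: int
    t_min: float
    t_max: float
    period: Optional[float] = None
    n_seasonal: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("legendre", "bspline_seasonal"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.d < 1:
            raise ValueError("basis dimension d must be >= 1")
        if not self.t_min < self.t_max:
            raise ValueError("need t_min < t_max")
        if self.kind == "bspline_seasonal":
            if self.period is None or self.period <= 0:
                raise ValueError("seasonal basis needs a positive period")
            if self.n_seasonal is None or not (1 <= self.n_seasonal <= self.d):
                raise ValueError("need 1 <= n_seasonal <= d")
            n_trend = self.d - self.n_seasonal
            if n_trend not in (0,) and n_trend < 4:
                raise ValueError("trend block needs 0 or >= 4 cubic B-splines")

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, dct):
        return cls(**dct)


def _cardinal_cubic(x):
    """Cardinal cubic B-spline N(x) with support [0, 4] and unit knot spacing."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    m = (x >= 0) & (x < 1)
    out[m] = x[m] ** 3 / 6.0
    m = (x >= 1) & (x < 2)
    u = x[m] - 1.0
    out[m] = (-3 * u**3 + 3 * u**2 + 3 * u + 1) / 6.0
    m = (x >= 2) & (x < 3)
    u = x[m] - 2.0
    out[m] = (3 * u**3 - 6 * u**2 + 4) / 6.0
    m = (x >= 3) & (x < 4)
    u = 1.0 - (x[m] - 3.0)
    out[m] = u**3 / 6.0
    return out


def _periodic_block(t, period, n_seasonal):
    """n_seasonal periodic cubic B-splines of the given period.

    Basis j is the periodisation of the cardinal cubic B-spline on a uniform
    circular knot grid with n_seasonal knots per period, so rows at t and
    t + period are identical by construction.
    """
    s = np.mod(np.asarray(t, dtype=float), period) / (period / n_seasonal)
    cols = []
    for j in range(n_seasonal):
        # wrap the support [j, j+4) around the circle of circumference
        # n_seasonal; for n_seasonal < 4 the support self-overlaps and the
        # wrapped copies are summed
        x = np.mod(s - j, n_seasonal)
        col = _cardinal_cubic(x)
        shift = n_seasonal
        while shift < 4:
            col = col + _cardinal_cubic(x + shift)
            shift += n_seasonal
        cols.append(col)
    return np.column_stack(cols)


def _trend_block(t, t_min, t_max, n_trend):
    """n_trend clamped cubic B-splines with equispaced interior knots."""
    k = 3
    n_interior = n_trend - (k + 1)
    interior = np.linspace(t_min, t_max, n_interior + 2)[1:-1]
    knots = np.concatenate([[t_min] * (k + 1), interior, [t_max] * (k + 1)])
    # design_matrix is strict about the half-open last interval; nudge t_max
    tt = np.minimum(np.asarray(t, dtype=float), t_max - 1e-12 * max(1.0, abs(t_max)))
    return BSpline.design_matrix(tt, knots, k).toarray()


def design_matrix(spec: BasisSpec, t) -> np.ndarray:
    """Evaluate the basis at times ``t``; returns an ``m x d`` matrix.

    Raises ``ValueError`` for times outside ``[t_min, t_max]``; an empty
    ``t`` yields a valid ``0 x d`` matrix.
    """
    t = np.asarray(t, dtype=float).ravel()
    if t.size == 0:
        return np.zeros((0, spec.d))
    tol = 1e-9 * max(1.0, abs(spec.t_min), abs(spec.t_max))
    if t.min() < spec.t_min - tol or t.max() > spec.t_max + tol:
        raise ValueError(
            f"time outside basis domain [{spec.t_min}, {spec.t_max}]"
        )
    t = np.clip(t, spec.t_min, spec.t_max)
    if spec.kind == "legendre":
        x = 2.0 * (t - spec.t_min) / (spec.t_max - spec.t_min) - 1.0
        return npleg.legvander(x, spec.d - 1)
    n_seasonal = spec.n_seasonal
    n_trend = spec.d - n_seasonal
    blocks = [_periodic_block(t, spec.period, n_seasonal)]
    if n_trend > 0:
        blocks.append(_trend_block(t, spec.t_min, spec.t_max, n_trend))
    return np.column_stack(blocks)
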