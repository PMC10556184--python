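"""Vectorised profiled-REML solver for random-intercept mixed models.

Per-sample tests inside cross-validation localization and cluster-based
permutation testing need thousands to millions of random-intercept-only
linear mixed-model fits; a general-purpose mixed-model optimizer is orders
of magnitude too slow for that. This module fits the model

    y = X beta + Z u + e,   u_g ~ N(0, s2_u),  e ~ N(0, s2)

with one random intercept per group, by profiling beta and s2 out of the
REML criterion and maximising over the variance ratio lam = s2_u / s2 on a
dense grid. For a single grouping factor the covariance inverse has the
closed Woodbury form

    V^-1 = I - sum_g c_g J_g,   c_g = lam / (1 + lam * m_g)

(J_g the all-ones block of group g, m_g its size), which reduces every
quantity to per-group sums; many response vectors sharing one design are
solved simultaneously.

The general-purpose route (statsmodels MixedLM) remains the estimation
engine for final models; agreement between the two is covered by tests.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["RandomInterceptGLS"]

_DEFAULT_GRID = np.concatenate([[0.0], np.logspace(-4.0, 4.0, 49)])


class RandomInterceptGLS:
    """Profiled-REML random-intercept GLS for a fixed design matrix.

    Parameters
    ----------
    X
        ``n x p`` fixed-effects design (including the intercept column).
    groups
        Length-``n`` array of group labels (participants).
    lam_grid
        Grid of candidate variance ratios ``s2_u / s2``; the default spans
        1e-4 to 1e4 plus the OLS boundary 0.
    """

    def __init__(self, X: np.ndarray, groups, lam_grid: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.X = X
        self.n, self.p = X.shape
        codes, self.group_index = np.unique(np.asarray(groups), return_inverse=True)
        self.n_groups = codes.size
        self.m = np.bincount(self.group_index).astype(float)  # group sizes
        self.lam_grid = _DEFAULT_GRID if lam_grid is None else np.asarray(lam_grid)
        self.XtX = X.T @ X
        # per-group column sums of X: (G, p)
        self.Sx = np.zeros((self.n_groups, self.p))
        np.add.at(self.Sx, self.group_index, X)
        # per-lambda cached quantities
        self._c = self.lam_grid[:, None] / (1.0 + self.lam_grid[:, None] * self.m)
        self._logdetV = np.log1p(np.outer(self.lam_grid, self.m)).sum(axis=1)
        self._A = np.empty((self.lam_grid.size, self.p, self.p))
        self._logdetA = np.empty(self.lam_grid.size)
        for i in range(self.lam_grid.size):
            A = self.XtX - (self.Sx * self._c[i][:, None]).T @ self.Sx
            self._A[i] = A
            sign, ld = np.linalg.slogdet(A)
            self._logdetA[i] = ld if sign > 0 else np.inf

    def fit_many(self, Y: np.ndarray) -> dict:
        """Fit every column of ``Y`` (``n x S``); returns arrays keyed by
        ``beta`` (p x S), ``se``, ``z``, ``p`` (all p x S), ``lam`` (S,),
        ``sigma2`` (S,)."""
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if Y.shape[0] != self.n:
            raise ValueError("Y rows must match the design")
        S = Y.shape[1]
        XtY = self.X.T @ Y                       # (p, S)
        Sy = np.zeros((self.n_groups, S))
        np.add.at(Sy, self.group_index, Y)
        yty = np.einsum("ns,ns->s", Y, Y)        # (S,)
        Sy2 = Sy ** 2

        best_ll = np.full(S, -np.inf)
        best_i = np.zeros(S, dtype=int)
        dof = self.n - self.p
        for i, lam in enumerate(self.lam_grid):
            c = self._c[i]
            B = XtY - self.Sx.T @ (c[:, None] * Sy)          # (p, S)
            beta = np.linalg.solve(self._A[i], B)            # (p, S)
            qy = yty - c @ Sy2
            rss = np.maximum(qy - np.einsum("ps,ps->s", B, beta), 1e-300)
            ll = -0.5 * (dof * np.log(rss) + self._logdetV[i] + self._logdetA[i])
            better = ll > best_ll
            best_ll[better] = ll[better]
            best_i[better] = i
        # recompute estimates at each sample's best lambda
        beta = np.empty((self.p, S))
        se = np.empty((self.p, S))
        sigma2 = np.empty(S)
        for i in np.unique(best_i):
            sel = best_i == i
            c = self._c[i]
            B = XtY[:, sel] - self.Sx.T @ (c[:, None] * Sy[:, sel])
            Ainv = np.linalg.inv(self._A[i])
            b = Ainv @ B
            qy = yty[sel] - c @ Sy2[:, sel]
            rss = np.maximum(qy - np.einsum("ps,ps->s", B, b), 1e-300)
            s2 = rss / dof
            beta[:, sel] = b
            sigma2[sel] = s2
            se[:, sel] = np.sqrt(np.outer(np.diag(Ainv), s2))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        p = 2.0 * sps.norm.sf(np.abs(z))
        return {
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "lam": self.lam_grid[best_i],
            "sigma2": sigma2,
        }

    def fit_one(self, y: np.ndarray) -> dict:
        out = self.fit_many(np.asarray(y, dtype=float)[:, None])
        return {k: (v[..., 0] if np.ndim(v) else v) for k, v in out.items()}
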