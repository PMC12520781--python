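"""Penalized cubic regression splines for Gaussian additive trend models.

Eilers–Marx style P-splines: a cubic B-spline basis of fixed dimension with a
second-order difference penalty, smoothing parameters chosen by generalized
cross-validation (GCV), one penalty per smooth block so that by-factor smooths
(one curve per region or trait class) get their own amount of smoothing.
Posterior (Bayesian) covariance of the coefficients is used for prediction
intervals, and model AIC is computed from effective degrees of freedom, the
conventions mgcv users expect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

LOG10_LAMBDA_GRID = np.linspace(-4.0, 7.0, 23)


def gaussian_aic(n: int, rss: float, edf: float) -> float:
    """AIC of a Gaussian fit from its RSS and effective degrees of freedom.

    Uses the ML variance estimate; +1 counts the variance parameter, so the
    value is comparable between OLS fits (edf = #coefficients) and penalized
    smooths (edf = trace of the hat matrix).
    """
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    return -2.0 * loglik + 2.0 * (edf + 1.0)


class SplineBasis:
    """Cubic B-spline basis of dimension ``k`` over the observed x range."""

    def __init__(self, x: np.ndarray, k: int):
        if k < 4:
            raise ValueError("cubic basis needs k >= 4")
        x = np.asarray(x, dtype=float)
        self.lo, self.hi = float(x.min()), float(x.max())
        if self.hi <= self.lo:
            raise ValueError("degenerate x range for spline basis")
        degree = 3
        n_interior = k - degree - 1
        interior = np.linspace(self.lo, self.hi, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [[self.lo] * (degree + 1), interior, [self.hi] * (degree + 1)]
        )
        self.k = k
        self.degree = degree

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.lo, self.hi)
        return BSpline.design_matrix(x, self.knots, self.degree).toarray()

    def penalty(self) -> np.ndarray:
        D = np.diff(np.eye(self.k), n=2, axis=0)
        return D.T @ D


@dataclass
class SmoothBlock:
    """One penalized block: a (possibly by-factor) smooth of one variable."""

    var: str
    by: str | None  # factor column, or None for a global smooth
    level: object | None  # factor level this block applies to
    basis: SplineBasis
    col_means: np.ndarray = field(default=None)
    cols: slice = field(default=None)

    def rows(self, data) -> np.ndarray:
        if self.by is None:
            return np.ones(len(data), dtype=bool)
        return (data[self.by] == self.level).to_numpy()

    def block(self, data) -> np.ndarray:
        """Centered basis columns, zero outside this block's rows."""
        out = np.zeros((len(data), self.basis.k))
        m = self.rows(data)
        if m.any():
            out[m] = self.basis.design(data[self.var].to_numpy()[m]) - self.col_means
        return out


class AdditiveTrendModel:
    """Gaussian additive model: factor terms + P-spline smooths of one variable.

    ``factors`` enter as dummies (the first with a full set, later ones
    drop-first, mimicking treatment coding with per-level intercepts);
    ``smooths`` is a list of ``None`` (global smooth of ``x``) or a factor
    column name (one smooth per level of that factor).  Smooth blocks are
    centered within their rows so the factor terms carry the level means.
    """

    def __init__(self, data, response: str, x: str = "year",
                 factors: list[str] = ("region",), smooths=(None,),
                 n_knots: int = 10):
        self.response = response
        self.x = x
        self.factors = list(factors)
        self.smooth_spec = list(smooths)
        self.n_knots = n_knots
        self.data = data.reset_index(drop=True)
        self.levels = {f: sorted(self.data[f].unique()) for f in self.factors}
        self._assemble()

    def _assemble(self):
        data = self.data
        cols, names = [], []
        for j, f in enumerate(self.factors):
            levels = self.levels[f] if j == 0 else self.levels[f][1:]
            for lv in levels:
                cols.append((data[f] == lv).to_numpy(float))
                names.append(f"{f}[{lv}]")
        X_unpen = np.column_stack(cols)
        xall = data[self.x].to_numpy(float)
        self.blocks: list[SmoothBlock] = []
        parts = [X_unpen]
        start = X_unpen.shape[1]
        for by in self.smooth_spec:
            basis = SplineBasis(xall, self.n_knots)
            levels = [None] if by is None else self.levels[by]
            for lv in levels:
                blk = SmoothBlock(var=self.x, by=by, level=lv, basis=basis)
                m = blk.rows(data)
                if m.sum() < 3:
                    raise ValueError(f"too few rows for smooth by {by}={lv}")
                B = basis.design(xall[m])
                blk.col_means = B.mean(axis=0)
                blk.cols = slice(start, start + basis.k)
                start += basis.k
                self.blocks.append(blk)
                parts.append(blk.block(data))
                names += [f"s({self.x}"
                          + (f",by={by}[{lv}])" if by else ")")
                          + f".{i}" for i in range(basis.k)]
        self.X = np.column_stack(parts)
        self.names = names
        self.n_unpen = X_unpen.shape[1]
        self.y = data[self.response].to_numpy(float)

    # -- fitting ----------------------------------------------------------
    def _penalized_solve(self, lambdas):
        p = self.X.shape[1]
        P = np.zeros((p, p))
        for lam, blk in zip(lambdas, self.blocks):
            P[blk.cols, blk.cols] += lam * blk.basis.penalty()
        A = self.XtX + P
        ridge = 1e-10 * (np.trace(self.XtX) / p + 1.0)
        A[np.diag_indices_from(A)] += ridge
        try:
            c = cho_factor(A)
        except np.linalg.LinAlgError:
            A[np.diag_indices_from(A)] += 1e4 * ridge
            c = cho_factor(A)
        beta = cho_solve(c, self.Xty)
        rss = float(self.yty - 2 * beta @ self.Xty + beta @ self.XtX @ beta)
        rss = max(rss, 0.0)
        edf = float(np.trace(cho_solve(c, self.XtX)))
        return beta, rss, edf, c

    def fit(self, n_sweeps: int = 3, fixed_lambdas: dict | None = None):
        """GCV-select smoothing parameters, then solve.

        ``fixed_lambdas`` maps block indices to values held fixed during
        selection — used for nested-model comparisons where the shared
        smooths keep the penalty chosen under the smaller model.
        """
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        n = len(self.y)
        fixed_lambdas = fixed_lambdas or {}
        lambdas = np.ones(len(self.blocks))
        for b, lam in fixed_lambdas.items():
            lambdas[b] = lam
        if self.blocks:
            for _ in range(n_sweeps):
                for b in range(len(self.blocks)):
                    if b in fixed_lambdas:
                        continue
                    best = (np.inf, lambdas[b])
                    for ll in LOG10_LAMBDA_GRID:
                        lambdas[b] = 10.0 ** ll
                        _, rss, edf, _ = self._penalized_solve(lambdas)
                        denom = max(n - edf, 1e-8)
                        gcv = n * rss / denom**2
                        if gcv < best[0]:
                            best = (gcv, lambdas[b])
                    lambdas[b] = best[1]
        self.lambdas = lambdas
        beta, rss, edf, c = self._penalized_solve(lambdas)
        self.beta = beta
        self.rss = rss
        self.edf = edf
        self.n = n
        self.sigma2 = rss / max(n - edf, 1e-8)
        p = self.X.shape[1]
        self.Vb = self.sigma2 * cho_solve(c, np.eye(p))  # Bayesian posterior cov
        self.aic = gaussian_aic(n, rss, edf)
        self.fitted = self.X @ beta
        return self

    # -- prediction -------------------------------------------------------
    def design_for(self, newdata) -> np.ndarray:
        cols = []
        for j, f in enumerate(self.factors):
            levels = self.levels[f] if j == 0 else self.levels[f][1:]
            for lv in levels:
                cols.append((newdata[f] == lv).to_numpy(float))
        X0 = [np.column_stack(cols)]
        for blk in self.blocks:
            X0.append(blk.block(newdata))
        return np.column_stack(X0)

    def predict(self, newdata, cov: bool = False):
        X0 = self.design_for(newdata)
        mu = X0 @ self.beta
        if not cov:
            return mu
        return mu, X0 @ self.Vb @ X0.T
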