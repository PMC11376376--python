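"""Exact profiled REML/ML for the one-random-intercept linear mixed model.

The model is y = X beta + Z u + e with u ~ N(0, sigma_u^2 I) over grouping
levels and e ~ N(0, sigma_e^2 I). Writing delta = sigma_u^2 / sigma_e^2, the
marginal covariance is sigma_e^2 (I + delta Z Z'), whose inverse is available
in closed form per group (Woodbury), so the likelihood profiles down to a 1-D
search over log(delta). This is the engine behind both qPCR repeatability
(X = intercept, groups = genotypes) and the reporter-assay 2x2 model
(X = treatment-coded factors, groups = experiments).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .exceptions import DesignError, EstimationError

LOG_DELTA_BOUNDS = (-12.0, 12.0)  # natural-log bounds of the variance ratio
_GRID_SIZE = 65


@dataclass
class RandomInterceptFit:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    df_resid: int
    reml: bool

    def wald_table(self, names) -> dict:
        """Wald t-tests per fixed effect with residual degrees of freedom."""
        se = np.sqrt(np.maximum(np.diag(self.cov_beta), 0.0))
        # degenerate zero-residual fits: a numerically-zero effect with zero
        # standard error is "no effect", not an infinite t
        null_effect = np.abs(self.beta) <= 1e-10 * max(1.0, float(np.max(np.abs(self.beta))))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, self.beta / np.where(se > 0, se, 1.0),
                            np.where(null_effect, 0.0, np.inf * np.sign(self.beta)))
        pval = 2.0 * stats.t.sf(np.abs(tval), self.df_resid)
        return {
            name: {"estimate": float(b), "se": float(s), "t": float(t), "p": float(p)}
            for name, b, s, t, p in zip(names, self.beta, se, tval, pval)
        }


def _group_stats(X: np.ndarray, y: np.ndarray, codes: np.ndarray, n_groups: int):
    """Per-group cross-products needed by the Woodbury identity."""
    p = X.shape[1]
    sx = np.zeros((n_groups, p))
    for j in range(p):
        sx[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_groups)
    sy = np.bincount(codes, weights=y, minlength=n_groups)
    nj = np.bincount(codes, minlength=n_groups).astype(float)
    return sx, sy, nj


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    reml: bool = True,
) -> RandomInterceptFit:
    """Fit the random-intercept LMM by profiled (RE)ML.

    Parameters are estimated exactly up to the 1-D optimizer tolerance; the
    variance ratio is searched on log(delta) in [-12, 12] with a 65-point grid
    followed by bounded Brent refinement, so the fit is deterministic.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.shape[0]:
        raise DesignError("X and y have different numbers of observations")
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[ok], X[ok]
    codes, levels = _factorize(np.asarray(groups)[ok])
    n, p = X.shape
    n_groups = len(levels)
    if n <= p:
        raise EstimationError("not enough observations to fit the model")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("fixed-effect design matrix is rank deficient")

    xtx = X.T @ X
    xty = X.T @ y
    yty = float(y @ y)
    sx, sy, nj = _group_stats(X, y, codes, n_groups)
    df = n - p
    _, logdet_xtx = np.linalg.slogdet(xtx)

    def profile(log_delta: float):
        delta = np.exp(log_delta)
        c = delta / (1.0 + nj * delta)  # per-group Woodbury coefficient
        A = xtx - (sx * c[:, None]).T @ sx
        b = xty - sx.T @ (c * sy)
        yy = yty - float(c @ (sy * sy))
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf, None
        rss = max(yy - float(beta @ b), 1e-300)
        sum_log = float(np.sum(np.log1p(nj * delta)))
        if reml:
            sigma_e2 = rss / df
            sign, logdet_a = np.linalg.slogdet(A)
            if sign <= 0:
                return np.inf, None
            # -2 restricted loglik up to an additive constant
            crit = df * np.log(2 * np.pi * sigma_e2) + df + sum_log + logdet_a - logdet_xtx
        else:
            sigma_e2 = rss / n
            crit = n * np.log(2 * np.pi * sigma_e2) + n + sum_log
        return crit, (beta, A, sigma_e2, delta)

    lo, hi = LOG_DELTA_BOUNDS
    grid = np.linspace(lo, hi, _GRID_SIZE)
    vals = np.array([profile(g)[0] for g in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b_ = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda t: profile(t)[0], bounds=(a, b_), method="bounded",
        options={"xatol": 1e-8},
    )
    best_t = res.x if res.fun <= vals[k] else grid[k]
    # a boundary optimum at the lower bound is effectively delta = 0
    crit, payload = profile(best_t)
    if payload is None:
        raise EstimationError("random-intercept REML failed to evaluate at the optimum")
    beta, A, sigma_e2, delta = payload
    if best_t <= lo + 1e-9:
        delta = 0.0
    if sigma_e2 * max(df, n) <= 1e-290:  # perfect fit: no residual variance
        sigma_e2 = 0.0
    sigma_u2 = delta * sigma_e2
    cov_beta = sigma_e2 * np.linalg.inv(A)
    return RandomInterceptFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        loglik=-0.5 * float(crit),
        converged=bool(np.isfinite(crit)),
        n_obs=n,
        n_groups=n_groups,
        df_resid=df,
        reml=reml,
    )


def _factorize(values: np.ndarray):
    levels, codes = np.unique(values, return_inverse=True)
    return codes, levels
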