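"""Two-level random-intercept logistic regression.

Model: for embryo j in cycle i,

    y_ij | b_i ~ Bernoulli(p_ij),  logit p_ij = x_ij' beta + b_i,
    b_i ~ N(0, sigma^2)

The marginal likelihood integrates the cycle-level intercept out with
adaptive Gauss–Hermite quadrature: per cluster the integrand's mode and
curvature are located by Newton's method (the conditional log-posterior is
concave in b) and the Hermite nodes are recentred and rescaled there, so a
modest number of nodes (15 by default) suffices even for large clusters.
Fixed effects and log(sigma) are maximised jointly with L-BFGS-B; Wald
standard errors come from the numerically differentiated observed
information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_fprime, approx_hess

__all__ = ["MixedLogitResult", "fit_mixed_logit_arrays", "ConvergenceError"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when the marginal-likelihood optimisation fails; carries the
    gradient norm rather than returning silent estimates."""


@dataclass
class MixedLogitResult:
    params: pd.DataFrame  # per coefficient: estimate, se, or_, ci_low, ci_high, p
    sigma: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    grad_norm: float
    n_quad: int
    separation_warnings: list[str]

    @property
    def odds_ratios(self) -> pd.Series:
        return self.params["or_"]


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Sort order, reduceat boundaries and group count."""
    codes, _ = pd.factorize(groups, sort=True)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) > 0])
    return order, starts, int(sorted_codes[-1]) + 1


class _AGQLoglik:
    """Negative marginal log-likelihood with warm-started inner modes."""

    def __init__(self, X, y, order, starts, n_groups, n_quad):
        self.X = X[order]
        self.y = y[order].astype(float)
        self.starts = starts
        self.G = n_groups
        g = np.zeros(self.X.shape[0], dtype=int)
        g[starts] = 1
        self.row_group = np.cumsum(g) - 1
        z, w = hermgauss(n_quad)
        self.z, self.logw = z, np.log(w)
        self.b_hat = np.zeros(self.G)

    def _modes(self, xb, inv_var):
        """Per-cluster Newton for the mode of the conditional posterior."""
        b = self.b_hat.copy()
        for _ in range(100):
            eta = xb + b[self.row_group]
            p = expit(eta)
            score = np.add.reduceat(self.y - p, self.starts) - b * inv_var
            info = np.add.reduceat(p * (1 - p), self.starts) + inv_var
            step = score / info
            b = b + step
            if np.max(np.abs(step)) < 1e-10:
                break
        self.b_hat = b
        eta = xb + b[self.row_group]
        p = expit(eta)
        info = np.add.reduceat(p * (1 - p), self.starts) + inv_var
        return b, 1.0 / np.sqrt(info)

    def loglik(self, beta, sigma):
        xb = self.X @ beta
        if sigma < 1e-8:
            eta = xb
            return float(np.sum(self.y * eta - np.logaddexp(0.0, eta)))
        inv_var = 1.0 / sigma**2
        b_hat, tau = self._modes(xb, inv_var)
        # nodes: b_hat + sqrt(2) * tau * z_k
        nodes = b_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]
        eta = xb[:, None] + nodes[self.row_group, :]
        ll_rows = self.y[:, None] * eta - np.logaddexp(0.0, eta)
        ll_gk = np.add.reduceat(ll_rows, self.starts, axis=0)
        ll_gk += -0.5 * nodes**2 * inv_var - np.log(sigma) - _LOG_SQRT_2PI
        li = (
            0.5 * np.log(2.0)
            + np.log(tau)
            + logsumexp(self.logw[None, :] + self.z[None, :] ** 2 + ll_gk, axis=1)
        )
        return float(li.sum())

    def neg_loglik_packed(self, params, fix_sigma=None):
        beta = params[:-1] if fix_sigma is None else params
        if fix_sigma is None:
            # clamp so overshooting line-search candidates stay evaluable
            sigma = float(np.exp(np.clip(params[-1], np.log(1e-8), np.log(20.0))))
        else:
            sigma = fix_sigma
        return -self.loglik(beta, sigma)


def fit_mixed_logit_arrays(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
    n_quad: int = 15,
    fix_sigma: float | None = None,
    start: np.ndarray | None = None,
) -> MixedLogitResult:
    """Fit the random-intercept logit on a prepared design matrix.

    ``X`` must already contain the intercept column.  ``fix_sigma`` pins the
    random-effect SD (0 collapses the model to ordinary logistic MLE).
    Raises :class:`ConvergenceError` on optimiser failure.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    n, p = X.shape
    if y.size != n or groups.size != n:
        raise ValueError("X, y, groups length mismatch")
    if not np.isfinite(X).all() or not np.isfinite(y).all():
        raise ValueError("non-finite values in the design matrix or outcome")
    names = names or [f"x{j}" for j in range(p)]
    order, starts, n_groups = _group_index(groups)

    # optimise on internally standardised covariates (constant columns such
    # as the intercept are left alone) and map estimates back afterwards
    const = X.std(axis=0) < 1e-12
    mean = np.where(const, 0.0, X.mean(axis=0))
    scale = np.where(const, 1.0, X.std(axis=0))
    Xs = (X - mean) / scale
    intercept_col = np.flatnonzero(const & (np.abs(X.mean(axis=0)) > 1e-12))
    fun = _AGQLoglik(Xs, y, order, starts, n_groups, n_quad)

    # back-transform matrix: beta_orig = A @ beta_std (sigma untouched)
    if not intercept_col.size:
        # without an intercept, centering would change the model: scale only
        mean = np.zeros(p)
        Xs = X / scale
        fun = _AGQLoglik(Xs, y, order, starts, n_groups, n_quad)
    A = np.diag(1.0 / scale)
    if intercept_col.size:
        ic = int(intercept_col[0])
        A[ic, :] = -mean / scale
        A[ic, ic] = 1.0 / X[:, ic].mean()

    # start at the ordinary-logit solution (cheap Newton via statsmodels)
    import statsmodels.api as sm

    try:
        with np.errstate(all="ignore"):
            beta0 = sm.Logit(y, Xs).fit(disp=0, maxiter=200).params
    except np.linalg.LinAlgError:  # e.g. perfect separation: start from 0
        beta0 = np.zeros(p)
    if start is not None:
        beta0 = np.linalg.solve(A, np.asarray(start, dtype=float)[:p])

    if fix_sigma is not None:
        x0 = beta0
        res = minimize(
            fun.neg_loglik_packed,
            x0,
            args=(fix_sigma,),
            method="L-BFGS-B",
            options={"maxiter": 1000, "maxfun": 100000, "ftol": 1e-13, "gtol": 1e-7},
        )
        sigma = float(fix_sigma)
        free = res.x
        beta_std = res.x
    else:
        x0 = np.r_[beta0, np.log(0.3)]
        bounds = [(None, None)] * p + [(np.log(1e-4), np.log(20.0))]
        res = minimize(
            fun.neg_loglik_packed,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 1000, "maxfun": 100000, "ftol": 1e-13, "gtol": 1e-7},
        )
        sigma = float(np.exp(res.x[p]))
        free = res.x
        beta_std = res.x[:p]

    # Newton polish: L-BFGS-B termination leaves ~1e-3 slack in the
    # coefficients; a few damped Newton steps on the numerically
    # differentiated objective tighten the solution to quadrature precision
    fval = fun.neg_loglik_packed(free, fix_sigma)
    for _ in range(15):
        g = approx_fprime(
            free, fun.neg_loglik_packed, kwargs={"fix_sigma": fix_sigma},
            centered=True,
        )
        if np.max(np.abs(g)) < 1e-7:
            break
        H = approx_hess(free, fun.neg_loglik_packed, kwargs={"fix_sigma": fix_sigma})
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        for _ in range(20):
            cand = free - t * step
            fcand = fun.neg_loglik_packed(cand, fix_sigma)
            if fcand <= fval + 1e-12:
                free, fval = cand, fcand
                break
            t /= 2
        else:
            break
    if fix_sigma is None:
        beta_std, sigma = free[:p], float(np.exp(free[p]))
    else:
        beta_std = free
    res.fun = fval
    beta = A @ beta_std

    grad = approx_fprime(free, fun.neg_loglik_packed, kwargs={"fix_sigma": fix_sigma})
    grad_norm = float(np.max(np.abs(grad)))
    if not res.success and grad_norm > 1e-2:
        raise ConvergenceError(
            f"mixed-logit optimisation failed: {res.message}; "
            f"max |gradient| = {grad_norm:.3e}"
        )

    # separation heuristic on standardised coefficients (log-odds per SD of
    # the predictor), so small-scale covariates are not falsely flagged
    separation = [
        f"possible separation: {names[j]} log-odds per SD = {beta_std[j]:.1f}"
        for j in range(p)
        if not const[j] and abs(beta_std[j]) > 5.0
    ]

    hess = approx_hess(free, fun.neg_loglik_packed, kwargs={"fix_sigma": fix_sigma})
    try:
        cov_std = np.linalg.inv(hess)
        cov_beta = A @ cov_std[:p, :p] @ A.T
        se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)

    from scipy.stats import norm

    zcrit = norm.ppf(0.975)
    zstat = np.divide(beta, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2.0 * norm.sf(np.abs(zstat))
    with np.errstate(over="ignore"):  # separated fits have infinite CIs
        table = pd.DataFrame(
            {
                "estimate": beta,
                "se": se,
                "or_": np.exp(beta),
                "ci_low": np.exp(beta - zcrit * se),
                "ci_high": np.exp(beta + zcrit * se),
                "p": pvals,
            },
            index=pd.Index(names, name="term"),
        )
    return MixedLogitResult(
        params=table,
        sigma=sigma,
        loglik=-float(res.fun),
        n_obs=n,
        n_groups=n_groups,
        converged=bool(res.success),
        grad_norm=grad_norm,
        n_quad=n_quad,
        separation_warnings=separation,
    )
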