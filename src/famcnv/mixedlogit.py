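"""Logistic regression with a family-level random intercept.

The model is

    y_ij ~ Bernoulli(logit^-1(x_ij' beta + u_i)),   u_i ~ N(0, sigma^2)

with ``i`` indexing families.  Families are independent, so the marginal
log-likelihood is a sum of one-dimensional integrals over each family's
intercept; these are evaluated by Gauss-Hermite quadrature (the quadrature
limit of the Laplace-type marginal-likelihood approximation, exact as the
node count grows).  The variance parameter is optimized on the sigma >= 0
scale with L-BFGS-B; Wald standard errors for the fixed effects come from the
numerically differentiated Hessian of the negative log-likelihood at the
optimum, holding sigma at its estimate when it sits on the zero boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats


@dataclass
class MixedLogitResult:
    coef: np.ndarray
    se: np.ndarray
    sigma: float
    loglik: float
    converged: bool
    n_iter: int

    def wald_p(self, index: int) -> float:
        se = self.se[index]
        if not np.isfinite(se) or se <= 0:
            return np.nan
        z = self.coef[index] / se
        return float(2.0 * stats.norm.sf(abs(z)))


def _negative_loglik(
    params: np.ndarray,
    X: np.ndarray,
    signs: np.ndarray,
    fam_starts: np.ndarray,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    beta, sigma = params[:-1], params[-1]
    eta = X @ beta  # (n,)
    shifted = signs[:, None] * (eta[:, None] + np.sqrt(2.0) * sigma * nodes[None, :])
    logp = -np.logaddexp(0.0, -shifted)  # log Bernoulli likelihood per node
    fam_loglik = np.add.reduceat(logp, fam_starts, axis=0)  # (F, K)
    per_family = special.logsumexp(fam_loglik + log_weights[None, :], axis=1)
    return -float(per_family.sum())


def fit_logistic_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 25,
    max_iter: int = 100,
    gtol: float = 1e-6,
) -> MixedLogitResult:
    """Fit the random-intercept logistic model by quadrature ML.

    ``X`` must include the intercept column.  ``groups`` are family labels.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    _, fam_starts = np.unique(groups, return_index=True)
    fam_starts = np.sort(fam_starts)
    signs = 2.0 * y - 1.0

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)

    def nll(params: np.ndarray) -> float:
        return _negative_loglik(params, X, signs, fam_starts, nodes, log_weights)

    p = X.shape[1]
    x0 = np.concatenate([np.zeros(p), [0.5]])
    bounds = [(None, None)] * p + [(0.0, 10.0)]
    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-12},
    )
    coef = res.x[:p]
    sigma = float(res.x[-1])

    # Hessian of the nll over beta (sigma held at its estimate), by central
    # finite differences; sigma at the zero boundary would otherwise make the
    # full Hessian singular.
    h = 1e-4 * np.maximum(1.0, np.abs(coef))
    hess = np.empty((p, p))
    for i in range(p):
        for j in range(i, p):
            pp = res.x.copy(); pp[i] += h[i]; pp[j] += h[j]
            pm = res.x.copy(); pm[i] += h[i]; pm[j] -= h[j]
            mp = res.x.copy(); mp[i] -= h[i]; mp[j] += h[j]
            mm = res.x.copy(); mm[i] -= h[i]; mm[j] -= h[j]
            hess[i, j] = hess[j, i] = (nll(pp) - nll(pm) - nll(mp) + nll(mm)) / (
                4.0 * h[i] * h[j]
            )
    se = np.full(p, np.nan)
    pos_def = False
    try:
        eigvals = np.linalg.eigvalsh(hess)
        if np.all(eigvals > 0):
            pos_def = True
            se = np.sqrt(np.diag(np.linalg.inv(hess)))
    except np.linalg.LinAlgError:
        pass

    converged = bool(
        res.success
        and np.all(np.isfinite(res.x))
        and np.all(np.abs(coef) < 15.0)
        and pos_def
        and np.all(np.isfinite(se))
    )
    return MixedLogitResult(
        coef=coef,
        se=se,
        sigma=sigma,
        loglik=-float(res.fun),
        converged=converged,
        n_iter=int(res.nit),
    )


def marginal_loglik(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    beta: np.ndarray,
    sigma: float,
    n_quad: int = 25,
) -> float:
    """Marginal log-likelihood at given parameters (testing hook)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    order = np.argsort(groups, kind="stable")
    y, X, groups = y[order], X[order], groups[order]
    _, fam_starts = np.unique(groups, return_index=True)
    fam_starts = np.sort(fam_starts)
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)
    params = np.concatenate([np.asarray(beta, dtype=float), [sigma]])
    return -_negative_loglik(params, X, 2.0 * y - 1.0, fam_starts, nodes, log_weights)
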