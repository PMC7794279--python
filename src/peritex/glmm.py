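"""Binomial GLMM with independent random effects, Laplace approximation.

Maximum-likelihood estimation of logit-link binomial mixed models with
diagonal random-effect covariance (no correlations between random
effects), the model family used for the log-odds-ratio analysis of trial
data.  The implementation follows the standard two-level scheme:

* random effects are expressed spherically, ``u = diag(lambda) v`` with
  ``v ~ N(0, I)``, so zero variances are handled without singularities;
* for a given vector of random-effect SDs ``lambda``, the fixed effects
  and spherical modes ``(beta, v)`` are found by a penalized Newton
  iteration (concave objective);
* the Laplace log-marginal-likelihood is
  ``ll(beta, v) - v'v/2 - log det(L' W L + I)/2`` with ``L = Z
  diag(lambda)`` and ``W`` the binomial IRLS weights at the mode;
* the SDs are optimized in an outer bounded quasi-Newton loop.

The binomial coefficient constant is omitted from the reported
log-likelihood; it cancels in likelihood-ratio tests and profile
intervals.  P-values come from the likelihood-ratio test of the full
model against the model with one fixed effect deleted (random structure
unchanged), and confidence intervals from profile likelihood with a Wald
fallback (flagged) when profiling fails.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = ["RandomTerm", "GLMMResult", "fit_laplace_glmm"]

_SIGMA_MAX = 20.0


@dataclass
class RandomTerm:
    """One grouping factor with its random-effect design.

    ``groups`` holds the level code (0..n_levels-1) of every observation;
    ``design`` the per-observation covariate values of the random effects
    (a column of ones for a random intercept plus one column per random
    slope); each design column has its own variance parameter.
    """

    name: str
    groups: np.ndarray
    design: np.ndarray
    col_names: list[str]

    @property
    def n_levels(self) -> int:
        return int(self.groups.max()) + 1

    @property
    def n_cols(self) -> int:
        return self.design.shape[1]


@dataclass
class GLMMResult:
    beta: np.ndarray
    beta_names: list[str]
    sigma: np.ndarray
    sigma_names: list[str]
    loglik: float
    converged: bool
    beta_cov: np.ndarray  # Laplace (Wald) covariance of fixed effects
    n_obs: int


def _expand_z(terms: list[RandomTerm], n: int) -> tuple[np.ndarray, np.ndarray]:
    """Dense random-effect design Z and the variance-class index per column."""
    cols = []
    classes = []
    cls = 0
    for term in terms:
        for j in range(term.n_cols):
            block = np.zeros((n, term.n_levels))
            block[np.arange(n), term.groups] = term.design[:, j]
            cols.append(block)
            classes.extend([cls] * term.n_levels)
            cls += 1
    if not cols:
        return np.zeros((n, 0)), np.array([], dtype=int)
    return np.concatenate(cols, axis=1), np.asarray(classes, dtype=int)


def _binom_ll(eta: np.ndarray, y: np.ndarray, m: np.ndarray) -> float:
    # log-likelihood without the binomial coefficient
    return float(np.sum(y * eta - m * np.logaddexp(0.0, eta)))


def _inner_mode(
    X: np.ndarray,
    Z: np.ndarray,
    classes: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    sigma: np.ndarray,
    beta0: np.ndarray,
    v0: np.ndarray,
    offset: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    """Penalized Newton for (beta, v) at fixed sigma; returns mode and Laplace ll."""
    lam = sigma[classes] if classes.size else np.zeros(0)
    L = Z * lam  # Z diag(lambda)
    p_fix = X.shape[1]
    q = L.shape[1]
    A = np.concatenate([X, L], axis=1)
    theta = np.concatenate([beta0, v0])

    def objective(th):
        eta = A @ th + offset
        return _binom_ll(eta, y, m) - 0.5 * float(th[p_fix:] @ th[p_fix:])

    obj = objective(theta)
    for _ in range(max_iter):
        eta = A @ theta + offset
        mu = m / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu / np.maximum(m, 1e-300))
        grad = A.T @ (y - mu)
        grad[p_fix:] -= theta[p_fix:]
        H = (A * w[:, None]).T @ A
        H[p_fix:, p_fix:] += np.eye(q)
        H[np.diag_indices_from(H)] += 1e-12
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving
        t = 1.0
        for _ in range(30):
            cand = theta + t * step
            cobj = objective(cand)
            if cobj >= obj - 1e-14:
                break
            t /= 2
        moved = abs(cobj - obj)
        theta, obj = cand, cobj
        if moved < tol * (1 + abs(obj)):
            break

    beta, v = theta[:p_fix], theta[p_fix:]
    eta = A @ theta + offset
    mu = m / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu / np.maximum(m, 1e-300))
    if q:
        M = (L * w[:, None]).T @ L + np.eye(q)
        sign, logdet = np.linalg.slogdet(M)
    else:
        logdet = 0.0
    lap = _binom_ll(eta, y, m) - 0.5 * float(v @ v) - 0.5 * logdet
    # Wald covariance of beta from the joint Hessian
    H = (np.concatenate([X, L], axis=1) * w[:, None]).T @ np.concatenate([X, L], axis=1)
    H[p_fix:, p_fix:] += np.eye(q)
    H[np.diag_indices_from(H)] += 1e-12
    try:
        Hinv = np.linalg.inv(H)
        beta_cov = Hinv[:p_fix, :p_fix]
    except np.linalg.LinAlgError:
        beta_cov = np.full((p_fix, p_fix), np.nan)
    return beta, v, lap, beta_cov


def fit_laplace_glmm(
    X: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    terms: list[RandomTerm],
    beta_names: list[str] | None = None,
    offset: np.ndarray | None = None,
    sigma0: float = 0.5,
) -> GLMMResult:
    """Fit the mixed model; ``y`` successes out of ``m`` trials per row."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = np.zeros(n)
    Z, classes = _expand_z(terms, n)
    n_sigma = int(classes.max()) + 1 if classes.size else 0
    sigma_names = [
        f"{t.name}:{c}" for t in terms for c in t.col_names
    ]
    if beta_names is None:
        beta_names = [f"b{j}" for j in range(p)]

    state = {"beta": np.zeros(p), "v": np.zeros(Z.shape[1])}

    def deviance(sigma: np.ndarray) -> float:
        beta, v, lap, _ = _inner_mode(
            X, Z, classes, y, m, sigma, state["beta"], state["v"], offset
        )
        state["beta"], state["v"] = beta, v
        return -2.0 * lap

    if n_sigma:
        res = optimize.minimize(
            deviance,
            np.full(n_sigma, sigma0),
            method="L-BFGS-B",
            bounds=[(0.0, _SIGMA_MAX)] * n_sigma,
            options={"ftol": 1e-11, "gtol": 1e-7, "maxiter": 200},
        )
        sigma = np.abs(res.x)
        converged = bool(res.success)

        # second stage: optimize (sigma, beta) in the outer loop with the
        # Laplace criterion integrating over the random effects only (the
        # convention of the reference mixed-model fits); beta at the joint
        # mode differs from this by a small Laplace correction.
        def deviance2(x: np.ndarray) -> float:
            sig, bet = np.abs(x[:n_sigma]), x[n_sigma:]
            _, v, lap, _ = _inner_mode(
                np.zeros((n, 0)), Z, classes, y, m, sig,
                np.zeros(0), state["v"], offset + X @ bet,
            )
            state["v"] = v
            return -2.0 * lap

        x0 = np.concatenate([sigma, state["beta"]])
        res2 = optimize.minimize(
            deviance2,
            x0,
            method="L-BFGS-B",
            bounds=[(0.0, _SIGMA_MAX)] * n_sigma + [(None, None)] * p,
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 300},
        )
        if res2.fun <= deviance(sigma) + 1e-9:
            sigma = np.abs(res2.x[:n_sigma])
            state["beta"] = res2.x[n_sigma:]
            converged = bool(res2.success)
    else:
        sigma = np.zeros(0)
        converged = True
        beta, v, lap, beta_cov = _inner_mode(
            X, Z, classes, y, m, sigma, state["beta"], state["v"], offset
        )
        return GLMMResult(
            beta=beta, beta_names=list(beta_names), sigma=sigma,
            sigma_names=sigma_names, loglik=lap, converged=converged,
            beta_cov=beta_cov, n_obs=n,
        )

    # final evaluation: v-mode at the fixed (sigma, beta), Laplace ll and
    # Wald covariance of beta from the full joint Hessian at that point
    beta = state["beta"]
    _, v, lap, _ = _inner_mode(
        np.zeros((n, 0)), Z, classes, y, m, sigma,
        np.zeros(0), state["v"], offset + X @ beta,
    )
    lam = sigma[classes] if classes.size else np.zeros(0)
    L = Z * lam
    eta = X @ beta + L @ v + offset
    mu = m / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu / np.maximum(m, 1e-300))
    A = np.concatenate([X, L], axis=1)
    H = (A * w[:, None]).T @ A
    H[p:, p:] += np.eye(L.shape[1])
    H[np.diag_indices_from(H)] += 1e-12
    try:
        beta_cov = np.linalg.inv(H)[:p, :p]
    except np.linalg.LinAlgError:  # pragma: no cover
        beta_cov = np.full((p, p), np.nan)
    return GLMMResult(
        beta=beta,
        beta_names=list(beta_names),
        sigma=sigma,
        sigma_names=sigma_names,
        loglik=lap,
        converged=converged,
        beta_cov=beta_cov,
        n_obs=n,
    )


def lrt_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    terms: list[RandomTerm],
    full: GLMMResult,
    col: int,
) -> float:
    """LRT p-value for fixed effect ``col`` (full vs. effect-deleted model)."""
    keep = [j for j in range(X.shape[1]) if j != col]
    reduced = fit_laplace_glmm(X[:, keep], y, m, terms)
    lr = 2.0 * (full.loglik - reduced.loglik)
    return float(stats.chi2.sf(max(lr, 0.0), df=1))


def profile_ci(
    X: np.ndarray,
    y: np.ndarray,
    m: np.ndarray,
    terms: list[RandomTerm],
    full: GLMMResult,
    col: int,
    level: float = 0.95,
) -> tuple[float, float, bool]:
    """Profile-likelihood CI for fixed effect ``col``.

    Returns (low, high, is_profile); falls back to the Wald interval with
    ``is_profile=False`` if the profile deviance cannot be bracketed.
    """
    crit = stats.chi2.ppf(level, df=1)
    bhat = full.beta[col]
    se = float(np.sqrt(max(full.beta_cov[col, col], 1e-12)))
    keep = [j for j in range(X.shape[1]) if j != col]
    Xr = X[:, keep]
    xj = X[:, col]
    dev_hat = -2.0 * full.loglik

    def profile_dev(b: float) -> float:
        r = fit_laplace_glmm(Xr, y, m, terms, offset=b * xj)
        return -2.0 * r.loglik

    def shifted(b: float) -> float:
        return profile_dev(b) - dev_hat - crit

    bounds = []
    ok = True
    for direction in (-1.0, 1.0):
        lo_b, hi_b = None, None
        step = max(se, 1e-3)
        prev = bhat
        for k in range(1, 30):
            cand = bhat + direction * step * k * 1.5
            if shifted(cand) > 0:
                lo_b, hi_b = (cand, prev) if direction < 0 else (prev, cand)
                break
            prev = cand
        if lo_b is None:
            ok = False
            break
        try:
            root = optimize.brentq(shifted, lo_b, hi_b, xtol=1e-4)
        except ValueError:
            ok = False
            break
        bounds.append(root)
    if ok and len(bounds) == 2:
        return float(min(bounds)), float(max(bounds)), True
    z = stats.norm.ppf(0.5 + level / 2)
    logger.warning("profile CI failed for column %d; Wald fallback", col)
    return float(bhat - z * se), float(bhat + z * se), False
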