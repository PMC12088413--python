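"""Laplace-approximated generalized linear mixed models with a single
scalar random intercept per group.

The models fitted here are GLMMs of the form

    y_i | u_{j(i)}  ~  Family(mean = exp(x_i' beta + u_j)),
    u_j             ~  Normal(0, sigma_u^2)   (independent across groups),

with log link throughout. Supported families are Gamma (shape ``k``),
Poisson, and negative binomial (NB2, dispersion ``theta``). The marginal
likelihood integrates each group's random intercept with a Laplace
approximation; because the random effect is a scalar per group, the
approximation is accurate and the inner optimisation reduces to a fast,
vectorised Newton iteration over all groups simultaneously.

This module exists because no installed Python package fits Gamma GLMMs;
plain GLMs (no random effect) are delegated to statsmodels elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = ["GLMMResult", "fit_glmm", "profile_gamma_shape", "gamma_glm_loglik"]

_FAMILIES = ("gamma", "poisson", "negbin")


@dataclass
class GLMMResult:
    """Fitted GLMM with a single random intercept.

    ``params`` holds the fixed effects in the order of the design-matrix
    columns; ``cov`` is the observed-information covariance of
    ``(params, extra)`` where ``extra`` collects the auxiliary parameters
    that were profiled jointly (log shape / log theta, and sigma_u when it
    is interior). ``cov_fixed`` is the fixed-effect block.
    """

    family: str
    param_names: list[str]
    params: np.ndarray
    cov_fixed: np.ndarray
    sigma_u: float
    shape: float | None  # Gamma shape k (None for count families)
    theta: float | None  # NB dispersion (None otherwise)
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    ranef_mode: np.ndarray = field(repr=False, default=None)
    group_labels: np.ndarray = field(repr=False, default=None)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_fixed))

    def wald_p(self) -> np.ndarray:
        z = self.params / self.se()
        return 2.0 * special.ndtr(-np.abs(z))


def _group_index(groups) -> tuple[np.ndarray, np.ndarray]:
    labels, idx = np.unique(np.asarray(groups), return_inverse=True)
    return labels, idx


def _cell_loglik(y, mu, family, aux):
    if family == "gamma":
        k = aux
        return (
            k * np.log(k)
            - special.gammaln(k)
            + (k - 1.0) * np.log(y)
            - k * y / mu
            - k * np.log(mu)
        )
    if family == "poisson":
        return y * np.log(mu) - mu - special.gammaln(y + 1.0)
    if family == "negbin":
        th = aux
        return (
            special.gammaln(y + th)
            - special.gammaln(th)
            - special.gammaln(y + 1.0)
            + th * np.log(th / (th + mu))
            + y * np.log(mu / (th + mu))
        )
    raise ValueError(f"unknown family {family!r}")


def _score_u(y, mu, family, aux):
    """d loglik_i / d u on the log-link scale (per observation)."""
    if family == "gamma":
        return aux * (y / mu - 1.0)
    if family == "poisson":
        return y - mu
    th = aux
    return y - (y + th) * mu / (mu + th)


def _fisher_u(y, mu, family, aux):
    """-d2 loglik_i / d u2 (per observation, nonnegative)."""
    if family == "gamma":
        return aux * y / mu
    if family == "poisson":
        return mu
    th = aux
    return (y + th) * th * mu / (mu + th) ** 2


def _solve_u(y, eta, gidx, n_groups, sigma2, family, aux, tol=1e-10, maxiter=100):
    """Vectorised Newton for the per-group posterior modes u_hat."""
    u = np.zeros(n_groups)
    for _ in range(maxiter):
        mu = np.exp(eta + u[gidx])
        g = np.bincount(gidx, weights=_score_u(y, mu, family, aux), minlength=n_groups)
        h = np.bincount(gidx, weights=_fisher_u(y, mu, family, aux), minlength=n_groups)
        if sigma2 > 0:
            g = g - u / sigma2
            h = h + 1.0 / sigma2
        else:
            return np.zeros(n_groups), h
        step = g / h
        step = np.clip(step, -2.0, 2.0)  # damp early oscillation
        u = u + step
        if np.max(np.abs(step)) < tol:
            break
    mu = np.exp(eta + u[gidx])
    h_data = np.bincount(gidx, weights=_fisher_u(y, mu, family, aux), minlength=n_groups)
    return u, h_data


def _marginal_loglik(y, X, gidx, n_groups, beta, sigma_u, family, aux):
    eta = X @ beta
    sigma2 = sigma_u * sigma_u
    u, h_data = _solve_u(y, eta, gidx, n_groups, sigma2, family, aux)
    mu = np.exp(eta + u[gidx])
    ll = float(np.sum(_cell_loglik(y, mu, family, aux)))
    if sigma2 > 0:
        # Laplace: joint at the mode plus curvature correction, written so the
        # sigma_u -> 0 limit reproduces the plain GLM log-likelihood exactly.
        ll -= float(np.sum(u * u) / (2.0 * sigma2))
        ll -= 0.5 * float(np.sum(np.log1p(sigma2 * h_data)))
    return ll, u


def _start_values(y, X, family):
    if family == "gamma":
        z = np.log(y)
    else:
        z = np.log(y + 0.5)
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    mu = np.exp(np.clip(X @ beta, -30, 30))
    if family == "gamma":
        cv2 = max(np.mean(((y - mu) / mu) ** 2), 1e-3)
        aux0 = np.log(1.0 / cv2)
    elif family == "negbin":
        excess = np.mean(((y - mu) ** 2 - mu) / np.maximum(mu, 1e-8) ** 2)
        aux0 = np.log(1.0 / max(excess, 0.05))
    else:
        aux0 = None
    return beta, aux0


def _numeric_hessian(f, x, rel_step=1e-4):
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), 1.0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def _nearest_psd(cov):
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 1e-12, None)
    return (v * w) @ v.T


def fit_glmm(
    y,
    X,
    groups,
    family: str = "gamma",
    param_names: list[str] | None = None,
    sigma_max: float = 5.0,
    fixed_sigma: float | None = None,
) -> GLMMResult:
    """Fit a log-link GLMM with one random intercept per group.

    Parameters
    ----------
    y, X, groups
        Response vector, design matrix (n x p), group labels (n,).
    family
        'gamma', 'poisson' or 'negbin'.
    fixed_sigma
        If given, sigma_u is held at this value (0 gives a plain ML GLM fit
        with the same likelihood machinery).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if family not in _FAMILIES:
        raise ValueError(f"family must be one of {_FAMILIES}, got {family!r}")
    if family == "gamma" and np.any(y <= 0):
        raise ValueError("Gamma family requires strictly positive responses")
    if family in ("poisson", "negbin"):
        if np.any(y < 0):
            raise ValueError("count families require nonnegative responses")
        if not np.all(y == np.round(y)):
            raise ValueError("count families require integer responses")
        if np.all(y == 0):
            raise ValueError("all-zero response: count model is degenerate")
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in response or design matrix")

    labels, gidx = _group_index(groups)
    n_groups = labels.size
    n, p = X.shape
    beta0, aux0 = _start_values(y, X, family)
    has_aux = aux0 is not None

    est_sigma = fixed_sigma is None

    def unpack(x):
        beta = x[:p]
        pos = p
        if est_sigma:
            sigma = x[pos]
            pos += 1
        else:
            sigma = fixed_sigma
        aux = np.exp(x[pos]) if has_aux else None
        return beta, sigma, aux

    def negloglik(x):
        beta, sigma, aux = unpack(x)
        try:
            ll, _ = _marginal_loglik(y, X, gidx, n_groups, beta, sigma, family, aux)
        except FloatingPointError:
            return 1e12
        if not np.isfinite(ll):
            return 1e12
        return -ll

    x0 = list(beta0)
    bounds = [(None, None)] * p
    if est_sigma:
        x0.append(0.1)
        bounds.append((0.0, sigma_max))
    if has_aux:
        x0.append(aux0)
        bounds.append((np.log(1e-3), np.log(1e6)))
    x0 = np.asarray(x0, dtype=float)

    with np.errstate(over="raise", invalid="raise"):
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-8},
        )
    beta_hat, sigma_hat, aux_hat = unpack(res.x)
    ll_hat, u_hat = _marginal_loglik(
        y, X, gidx, n_groups, beta_hat, sigma_hat, family, aux_hat
    )

    # Observed information. When sigma_u sits on its boundary (0) it is not
    # differentiable there; profile the Hessian over the remaining parameters.
    at_boundary = est_sigma and sigma_hat < 1e-5
    if at_boundary:
        free = [i for i in range(res.x.size) if i != p]
    else:
        free = list(range(res.x.size))

    def nll_free(xf):
        xfull = np.array(res.x, copy=True)
        xfull[free] = xf
        return negloglik(xfull)

    H = _numeric_hessian(nll_free, res.x[free])
    try:
        cov_free = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_free = np.linalg.pinv(H)
    cov_free = _nearest_psd(cov_free)
    cov_fixed = cov_free[:p, :p]

    k_params = res.x.size
    result = GLMMResult(
        family=family,
        param_names=param_names or [f"b{i}" for i in range(p)],
        params=beta_hat,
        cov_fixed=cov_fixed,
        sigma_u=float(sigma_hat),
        shape=float(aux_hat) if family == "gamma" else None,
        theta=float(aux_hat) if family == "negbin" else None,
        loglik=float(ll_hat),
        aic=float(2 * k_params - 2 * ll_hat),
        n_obs=n,
        n_groups=int(n_groups),
        converged=bool(res.success),
        ranef_mode=u_hat,
        group_labels=labels,
    )
    if not res.success and res.status != 1:  # status 1 = maxiter
        raise RuntimeError(f"GLMM optimisation failed: {res.message}")
    return result


def gamma_glm_loglik(y, mu, shape):
    """Gamma log-likelihood at given means and shape (no random effect)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(np.sum(_cell_loglik(y, mu, "gamma", shape)))


def profile_gamma_shape(y, mu):
    """ML Gamma shape given fitted means (profile over k only).

    For the log link the ML fixed effects do not depend on k, so a plain
    Gamma GLM's ML log-likelihood is obtained by profiling k afterwards.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)

    def neg(logk):
        return -gamma_glm_loglik(y, mu, np.exp(logk))

    res = optimize.minimize_scalar(neg, bounds=(np.log(1e-3), np.log(1e6)), method="bounded")
    k = float(np.exp(res.x))
    return k, -float(res.fun)
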