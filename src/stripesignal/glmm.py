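"""Binomial random-intercept GLMM with likelihood-ratio testing.

Fits logit models of a binary outcome with a Gaussian random intercept per
group by maximum likelihood, integrating the random effect with
Gauss-Hermite quadrature.  Used for the contest-outcome models, where the
grouping factor is the dyad.

Complete separation (a predictor that perfectly classifies the outcome)
makes the ML estimate diverge; it is detected up front and the model falls
back to a bias-reduced (Jeffreys-prior penalized, Firth-type) fixed-effects
logistic fit with a warning flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize as opt
import scipy.stats as st

__all__ = ["GlmmFit", "fit_binomial_glmm", "glmm_lrt", "firth_logistic"]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(21)
# probabilists' Hermite: integral f(u) phi(u) du = sum w_k f(t_k) / sqrt(2 pi)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


@dataclass
class GlmmFit:
    """A fitted binomial random-intercept GLMM (or its Firth fallback)."""

    params: pd.Series
    random_intercept_sd: float
    loglike: float
    n_obs: int
    n_groups: int
    separation: bool
    method: str  # "glmm" or "firth"


def _cluster_loglike(beta, log_sigma, y, X, group_idx, n_groups):
    sigma = np.exp(log_sigma)
    eta = X @ beta  # (n,)
    # (n, K) linear predictor across quadrature nodes
    u = sigma * _GH_NODES
    z = eta[:, None] + u[None, :]
    # log Bernoulli pmf, numerically stable
    logp = -np.logaddexp(0.0, -z)
    log1mp = -np.logaddexp(0.0, z)
    ll_obs = np.where(y[:, None] == 1, logp, log1mp)
    # sum within clusters -> (G, K)
    cluster_ll = np.zeros((n_groups, ll_obs.shape[1]))
    np.add.at(cluster_ll, group_idx, ll_obs)
    m = cluster_ll.max(axis=1, keepdims=True)
    lik = np.exp(cluster_ll - m) @ _GH_WEIGHTS
    return float(np.sum(m[:, 0] + np.log(lik)))


def _detect_separation(y: np.ndarray, X: pd.DataFrame) -> bool:
    """True if any single non-intercept predictor perfectly classifies y."""
    if y.min() == y.max():
        return True
    for c in X.columns:
        if c == "Intercept":
            continue
        col = X[c].to_numpy()
        df = pd.DataFrame({"x": col, "y": y})
        nun = df.groupby("x")["y"].nunique()
        if (nun == 1).all() and df["x"].nunique() > 1:
            return True
    return False


def fit_binomial_glmm(
    y: np.ndarray,
    X: pd.DataFrame,
    groups: np.ndarray,
    allow_fallback: bool = True,
) -> GlmmFit:
    """ML fit of logit(P(y=1)) = X beta + u_g, u_g ~ N(0, sigma^2)."""
    y = np.asarray(y, dtype=float)
    codes, _ = pd.factorize(groups)
    n_groups = codes.max() + 1
    Xm = X.to_numpy(dtype=float)

    separated = _detect_separation(y, X)
    if separated:
        if not allow_fallback:
            raise ValueError("complete separation detected")
        warnings.warn(
            "complete separation detected; falling back to bias-reduced "
            "fixed-effects logistic fit",
            stacklevel=2,
        )
        beta, ll = firth_logistic(y, Xm)
        return GlmmFit(
            params=pd.Series(beta, index=list(X.columns)),
            random_intercept_sd=0.0,
            loglike=ll,
            n_obs=len(y),
            n_groups=int(n_groups),
            separation=True,
            method="firth",
        )

    p = Xm.shape[1]

    def neg_ll(theta):
        return -_cluster_loglike(theta[:p], theta[p], y, Xm, codes, n_groups)

    # warm start at the plain logistic solution, small random-effect SD
    beta0, _ = firth_logistic(y, Xm, max_iter=25)
    theta0 = np.concatenate([beta0, [np.log(0.25)]])
    res = opt.minimize(neg_ll, theta0, method="L-BFGS-B", options={"maxiter": 500})
    beta = res.x[:p]
    sigma = float(np.exp(res.x[p]))
    return GlmmFit(
        params=pd.Series(beta, index=list(X.columns)),
        random_intercept_sd=sigma,
        loglike=-float(res.fun),
        n_obs=len(y),
        n_groups=int(n_groups),
        separation=False,
        method="glmm",
    )


def glmm_lrt(full: GlmmFit, reduced: GlmmFit, df: int = 1) -> tuple[float, float]:
    """Likelihood-ratio chi-square between nested fits of the same kind."""
    if full.method != reduced.method:
        raise ValueError("cannot compare fits from different methods")
    chi2 = max(2.0 * (full.loglike - reduced.loglike), 0.0)
    return chi2, float(st.chi2.sf(chi2, df))


def firth_logistic(
    y: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Jeffreys-prior penalized logistic regression (Firth correction).

    Returns the coefficient vector and the *unpenalized* log-likelihood at
    the penalized estimate.  Finite estimates exist even under complete
    separation.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(X @ beta, -30, 30)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return beta, ll
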