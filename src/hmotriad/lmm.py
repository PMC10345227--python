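"""Random-intercept linear mixed model fitted by REML.

The regression stage models each MSEL score as

    y_ij = x_ij' beta + b_i + e_ij,   b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma^2)

for infant i at visit j.  The covariance of a subject's visits is
``sigma^2 (I + theta J)`` with variance ratio ``theta = sigma_b^2/sigma^2``
and ``J`` the all-ones matrix, which inverts in closed form per subject:
``(I + theta J)^-1 = I - theta/(1 + n_i theta) J``.  The restricted
log-likelihood is profiled over ``beta`` (GLS) and ``sigma^2``, leaving a
one-dimensional REML criterion in ``theta`` minimized numerically on
[0, 1e3].  Wald tests use t statistics with ``df = n_obs - p_fixed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["LMMFit", "reml_loglik", "fit_lmm_reml", "wald_tests"]


@dataclass
class LMMFit:
    beta: np.ndarray          # fixed-effect estimates (effect sizes)
    se: np.ndarray
    tstat: np.ndarray
    pvalues: np.ndarray
    sigma_b2: float           # subject-intercept variance
    sigma2: float             # residual variance
    theta: float              # sigma_b2 / sigma2
    reml_loglik: float
    df: int
    n_obs: int
    n_subjects: int
    columns: list[str] | None = None


def _subject_blocks(subject_ids) -> list[np.ndarray]:
    ids = np.asarray(subject_ids)
    order: dict = {}
    for i, s in enumerate(ids):
        order.setdefault(s, []).append(i)
    return [np.asarray(ix) for ix in order.values()]


def _profile(theta: float, X: np.ndarray, y: np.ndarray,
             blocks: list[np.ndarray]):
    """Profiled REML pieces at a variance ratio theta.

    Returns (restricted loglik, beta_gls, XtWX, sigma2_hat).  ``W`` is the
    unit-scale precision ``(I + theta Z Z')^{-1}``, applied blockwise.
    """
    n, p = X.shape
    XtWX = np.zeros((p, p))
    XtWy = np.zeros(p)
    ytWy = 0.0
    logdetV = 0.0
    for ix in blocks:
        Xi, yi = X[ix], y[ix]
        ni = ix.size
        shrink = theta / (1.0 + ni * theta)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        XtWX += Xi.T @ Xi - shrink * np.outer(sx, sx)
        XtWy += Xi.T @ yi - shrink * sx * sy
        ytWy += float(yi @ yi) - shrink * sy * sy
        logdetV += np.log1p(ni * theta)
    sign, logdetXtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X' V^-1 X is singular")
    beta = np.linalg.solve(XtWX, XtWy)
    rss = max(ytWy - float(XtWy @ beta), 1e-300)
    sigma2 = rss / (n - p)
    ll = -0.5 * ((n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
                 + logdetV + logdetXtWX)
    return ll, beta, XtWX, sigma2


def reml_loglik(theta: float, X: np.ndarray, y: np.ndarray,
                subject_ids) -> float:
    """Restricted log-likelihood profiled over beta and sigma^2."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    ll, *_ = _profile(theta, X, y, _subject_blocks(subject_ids))
    return float(ll)


def fit_lmm_reml(X: np.ndarray, y: np.ndarray, subject_ids,
                 columns: list[str] | None = None,
                 theta_max: float = 1e3, xatol: float = 1e-10) -> LMMFit:
    """REML fit of the random-intercept model.

    The variance ratio is found by bounded scalar minimization of the
    negative restricted log-likelihood on [0, theta_max]; the boundary
    theta=0 (no subject variance) is allowed.  With only singleton subjects
    the ratio is unidentifiable: a warning is issued and the fit reduces to
    OLS.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("X and y have incompatible shapes")
    blocks = _subject_blocks(subject_ids)
    if len(blocks) < 2:
        raise ValueError("fit_lmm_reml requires >= 2 subjects")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n_obs={n} <= p_fixed={p}: model not estimable")

    if all(ix.size == 1 for ix in blocks):
        warnings.warn("all subjects have a single visit; the intercept "
                      "variance is unidentifiable -- fitting with theta=0 (OLS)",
                      RuntimeWarning)
        theta_hat = 0.0
    else:
        def nll(t):
            return -_profile(t, X, y, blocks)[0]

        res = optimize.minimize_scalar(nll, bounds=(0.0, theta_max),
                                       method="bounded",
                                       options={"xatol": xatol})
        theta_hat = float(res.x)
        # the bounded minimizer never probes the exact boundary; accept 0
        # when it is at least as good as the interior candidate
        if nll(0.0) <= res.fun:
            theta_hat = 0.0

    ll, beta, XtWX, sigma2 = _profile(theta_hat, X, y, blocks)
    cov = sigma2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    df = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df)
    return LMMFit(beta=beta, se=se, tstat=tstat, pvalues=pvals,
                  sigma_b2=theta_hat * sigma2, sigma2=sigma2,
                  theta=theta_hat, reml_loglik=float(ll), df=df,
                  n_obs=n, n_subjects=len(blocks), columns=columns)


def wald_tests(fit: LMMFit, roles: list[str] | None = None) -> pd.DataFrame:
    """Per-term effect sizes, SEs, t statistics and two-sided p-values."""
    names = fit.columns if fit.columns is not None else \
        [f"x{j}" for j in range(fit.beta.size)]
    out = pd.DataFrame({
        "term": names,
        "effect_size": fit.beta,
        "se": fit.se,
        "t": fit.tstat,
        "p": fit.pvalues,
    })
    if roles is not None:
        out.insert(1, "role", roles)
    return out
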