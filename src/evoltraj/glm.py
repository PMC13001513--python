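"""Batched binomial GLM fitting.

Genome scans fit the same small design matrix at every locus, so IRLS is
vectorized across loci: one batched weighted-least-squares solve per
iteration instead of hundreds of thousands of independent model fits.
Quasi-likelihood inference (dispersion from Pearson residuals) is layered
on top by the callers.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

_MU_EPS = 1e-8


def fit_binomial_many(y, n, X, max_iter=50, tol=1e-9):
    """Fit logit-link binomial GLMs at many loci sharing one design.

    Parameters
    ----------
    y, n : (L, S) arrays of successes and trials.
    X : (S, p) design matrix, common to all loci.

    Returns a dict with ``coef`` (L, p), ``cov_unscaled`` (L, p, p) —
    (X'WX)^-1 at the final iterate — ``deviance`` (L,), ``pearson`` (L,),
    ``ok`` (L,) estimability mask, and ``df_resid``.  Loci with no
    variation (all successes or all failures) are flagged not-ok.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    L, S = y.shape
    p = X.shape[1]
    if S <= p:
        raise ValueError(f"need more samples ({S}) than parameters ({p})")
    degenerate = (y.sum(axis=1) == 0) | ((n - y).sum(axis=1) == 0)

    eta = logit((y + 0.5) / (n + 1.0))
    coef = np.zeros((L, p))
    ridge = 1e-10 * np.eye(p)
    converged = np.zeros(L, dtype=bool)
    for _ in range(max_iter):
        mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
        W = n * mu * (1.0 - mu)
        z = eta + (y - n * mu) / W
        XtWX = np.einsum("sp,ls,sq->lpq", X, W, X, optimize=True)
        XtWz = np.einsum("sp,ls->lp", X, W * z, optimize=True)
        try:
            new = np.linalg.solve(XtWX + ridge, XtWz[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new = np.linalg.lstsq(
                (XtWX + ridge).reshape(-1, p, p)[0], XtWz[0], rcond=None
            )[0][None, :]
            new = np.broadcast_to(new, coef.shape).copy()
        delta = np.max(np.abs(new - coef), axis=1)
        coef = new
        eta = np.clip(coef @ X.T, -30.0, 30.0)
        converged = delta < tol
        if converged.all():
            break

    mu = np.clip(expit(eta), _MU_EPS, 1.0 - _MU_EPS)
    W = n * mu * (1.0 - mu)
    XtWX = np.einsum("sp,ls,sq->lpq", X, W, X, optimize=True)
    cov = np.linalg.pinv(XtWX + ridge)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / (n * mu)), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - n * mu)), 0.0)
    deviance = 2.0 * (t1 + t2).sum(axis=1)
    pearson = (((y - n * mu) ** 2) / W).sum(axis=1)
    finite = np.isfinite(coef).all(axis=1)
    ok = finite & ~degenerate
    return {
        "coef": coef,
        "cov_unscaled": cov,
        "deviance": deviance,
        "pearson": pearson,
        "ok": ok,
        "df_resid": S - p,
    }
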