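"""Per-locus beta-binomial GLMMs for antiparallel allele-frequency scans.

At every SNP the minor-allele count Y and coverage n are modelled as

    Y ~ BetaBinomial(n, p, rho),
    logit(p) = beta0 + beta1*T + beta2*G + beta3*(T*G) + u_rep,

with T the trajectory indicator (0 = A->C, 1 = C->A), G the number of
generations under the current regime, u_rep ~ N(0, sigma_u^2) a random
intercept per replicate population, and rho the beta-binomial intraclass
correlation (the overdispersion parameter, reported as "phi"; shapes are
a = p(1-rho)/rho, b = (1-p)(1-rho)/rho, so rho -> 0 recovers the
binomial).  The interaction beta3 captures reciprocal (antiparallel)
trajectories; a genome-wide scan Bonferroni-adjusts each term across
tested loci.

Estimation maximizes the Laplace-approximated marginal likelihood over
(beta, logit rho, log sigma_u); adaptive Gauss-Hermite quadrature is
available as a validation mode.  Inference uses Wald z-tests from a
finite-difference Hessian of the marginal log-likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logit, polygamma
from scipy.stats import norm, chi2

from .glm import fit_binomial_many
from .snp_io import SnpTable

logger = logging.getLogger(__name__)

# below this the beta-binomial is numerically indistinguishable from its
# binomial limit (and gammaln at shape ~1/rho loses precision), so the
# exact limit expression is used instead
_RHO_MIN = 1e-8
_SU_MIN = 1e-4

TERMS = ("intercept", "treatment", "generation", "interaction")


def bb_logpmf(y, n, p, rho, const=None):
    """Log pmf of BetaBinomial(n, p, rho); binomial in the rho -> 0 limit.

    ``const`` may carry the precomputed log binomial coefficient
    ln C(n, y) to avoid recomputing it in tight loops.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1.0 - 1e-12)
    if const is None:
        const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    if np.ndim(rho) == 0 and rho < _RHO_MIN:
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(y > 0, y * np.log(p), 0.0)
            t2 = np.where(n - y > 0, (n - y) * np.log1p(-p), 0.0)
        return const + t1 + t2
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return (
        const
        + gammaln(y + a) + gammaln(n - y + b) - gammaln(n + a + b)
        + gammaln(a + b) - gammaln(a) - gammaln(b)
    )


def bb_loglik(beta, phi, u, counts, design) -> float:
    """Conditional log-likelihood given fixed effects and random intercepts.

    ``counts`` is ``(minor, coverage)``; ``design`` a DataFrame with
    columns T, G, rep.  ``u`` maps replicate labels (in the order of
    ``design.rep.unique()``) to intercept offsets.
    """
    y, n = (np.asarray(a, dtype=float) for a in counts)
    if np.any(y < 0) or np.any(y > n):
        raise ValueError("counts must satisfy 0 <= minor <= coverage")
    if phi < 0:
        raise ValueError("phi must be non-negative")
    X = _design_matrix(design)
    rep_idx = _rep_index(design)
    eta = X @ np.asarray(beta, dtype=float) + np.asarray(u, dtype=float)[rep_idx]
    if not np.all(np.isfinite(eta)):
        bad = int(np.flatnonzero(~np.isfinite(eta))[0])
        raise ValueError(f"non-finite linear predictor at observation {bad}")
    return float(np.sum(bb_logpmf(y, n, expit(eta), phi)))


def _design_matrix(design: pd.DataFrame) -> np.ndarray:
    T = design["T"].to_numpy(float)
    G = design["G"].to_numpy(float)
    return np.column_stack([np.ones_like(T), T, G, T * G])


def _rep_index(design: pd.DataFrame) -> np.ndarray:
    _, idx = np.unique(design["rep"].to_numpy(), return_inverse=True)
    return idx


@dataclass
class BbFitResult:
    """Estimates for one locus: beta = (b0, b1, b2, b3) on the logit
    scale, Wald SEs and p-values per term, overdispersion phi (intraclass
    correlation), random-intercept variance sigma_u2, and the maximized
    marginal log-likelihood."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    phi: float
    sigma_u2: float
    loglik: float
    converged: bool
    reason: str = ""


class _MarginalNLL:
    """Negative Laplace-approximated marginal log-likelihood in
    theta = (coefs..., logit rho, log sigma_u), with warm-started inner
    Newton solves for the random-intercept modes."""

    def __init__(self, y, n, X, rep_idx):
        self.y = np.asarray(y, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.X = X
        self.rep_idx = rep_idx
        self.J = int(rep_idx.max()) + 1 if len(rep_idx) else 0
        self.k = X.shape[1]
        self.const = gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(
            self.n - self.y + 1
        )
        self._u = np.zeros(self.J)

    def _cond_ll_by_rep(self, eta0, u, rho):
        eta = eta0 + u[self.rep_idx]
        ll = bb_logpmf(self.y, self.n, expit(eta), rho, const=self.const)
        return np.bincount(self.rep_idx, weights=ll, minlength=self.J)

    def _score_info_by_rep(self, eta0, u, rho):
        """Per-replicate sums of d(ll)/d(eta) and d2(ll)/d(eta)2.

        With a = p·c, b = (1−p)·c, c = (1−rho)/rho (a+b constant in eta),
        the beta-binomial score in eta is c·p(1−p)·D with
        D = psi(y+a) − psi(a) − psi(n−y+b) + psi(b).
        """
        eta = eta0 + u[self.rep_idx]
        p = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        v = p * (1.0 - p)
        if rho < _RHO_MIN:
            g = self.y - self.n * p
            h = -self.n * v
        else:
            c = (1.0 - rho) / rho
            a = p * c
            b = (1.0 - p) * c
            D = digamma(self.y + a) - digamma(a) - digamma(self.n - self.y + b) + digamma(b)
            Dp = (polygamma(1, self.y + a) - polygamma(1, a)
                  + polygamma(1, self.n - self.y + b) - polygamma(1, b))
            cv = c * v
            g = cv * D
            h = cv * (1.0 - 2.0 * p) * D + cv * cv * Dp
        return (
            np.bincount(self.rep_idx, weights=g, minlength=self.J),
            np.bincount(self.rep_idx, weights=h, minlength=self.J),
        )

    def _solve_modes(self, eta0, rho, su):
        """Inner Newton for the per-replicate posterior modes u*."""
        u = self._u.copy()
        inv_v = 1.0 / (su * su)
        for _ in range(50):
            s, info = self._score_info_by_rep(eta0, u, rho)
            g1 = s - u * inv_v
            g2 = np.minimum(info - inv_v, -1e-8)
            step = np.clip(g1 / g2, -2.0, 2.0)
            u = u - step
            if np.max(np.abs(step)) < 1e-10:
                break
        self._u = u
        l0 = self._cond_ll_by_rep(eta0, u, rho)
        _, info = self._score_info_by_rep(eta0, u, rho)
        g2 = np.minimum(info - inv_v, -1e-8)
        return u, l0, g2

    def value(self, theta, quad_nodes=0):
        coefs = theta[: self.k]
        rho = float(expit(theta[self.k]))
        su = float(np.exp(theta[self.k + 1]))
        eta0 = self.X @ coefs
        u, l0, g2 = self._solve_modes(eta0, rho, su)
        log_prior = -0.5 * u * u / (su * su) - np.log(su) - 0.5 * np.log(2 * np.pi)
        if quad_nodes <= 1:
            # Laplace: g(u*) + 0.5 log(2 pi) - 0.5 log(-g'')
            contrib = l0 + log_prior + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(-g2)
        else:
            z, w = hermgauss(quad_nodes)
            s = 1.0 / np.sqrt(-g2)
            pts = u[:, None] + np.sqrt(2.0) * s[:, None] * z[None, :]
            vals = np.empty((self.J, quad_nodes))
            for q in range(quad_nodes):
                uq = pts[:, q]
                lq = self._cond_ll_by_rep(eta0, uq, rho)
                vals[:, q] = (
                    lq - 0.5 * uq * uq / (su * su) - np.log(su)
                    - 0.5 * np.log(2 * np.pi) + z[q] * z[q]
                )
            m = vals.max(axis=1)
            contrib = (
                m
                + np.log(np.sum(w[None, :] * np.exp(vals - m[:, None]), axis=1))
                + np.log(np.sqrt(2.0) * s)
            )
        val = -float(np.sum(contrib))
        return val if np.isfinite(val) else 1e12


def _numeric_hessian(fun, theta, rel_step=1e-4):
    k = len(theta)
    h = rel_step * (1.0 + np.abs(theta))
    H = np.empty((k, k))
    f0 = fun(theta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h[i]
        fpp = fun(theta + ei)
        fmm = fun(theta - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / (h[i] * h[i])
    for i, j in combinations(range(k), 2):
        ei = np.zeros(k)
        ej = np.zeros(k)
        ei[i] = h[i]
        ej[j] = h[j]
        H[i, j] = H[j, i] = (
            fun(theta + ei + ej) - fun(theta + ei - ej)
            - fun(theta - ei + ej) + fun(theta - ei - ej)
        ) / (4 * h[i] * h[j])
    return H


def _fit_bb_mixed(y, n, X, rep_idx, method="laplace", quad_nodes=15):
    """Maximize the marginal likelihood; returns (theta, nll, cov, ok)."""
    nll = _MarginalNLL(y, n, X, rep_idx)
    k = X.shape[1]
    nodes = quad_nodes if method == "aghq" else 0
    fun = lambda th: nll.value(th, quad_nodes=nodes)

    p_bar = np.clip(y.sum() / max(n.sum(), 1.0), 1e-4, 1 - 1e-4)
    base = np.zeros(k)
    base[0] = logit(p_bar)
    # warm start: quasibinomial GLM for beta, Pearson moments for rho
    try:
        glm = fit_binomial_many(y[None, :], n[None, :], X)
        if glm["ok"][0]:
            base = np.clip(glm["coef"][0], -10.0, 10.0)
        n_bar = max(float(n.mean()), 2.0)
        disp = glm["pearson"][0] / glm["df_resid"]
        rho0 = float(np.clip((disp - 1.0) / (n_bar - 1.0), 1e-3, 0.5))
    except (np.linalg.LinAlgError, ValueError):
        rho0 = 0.02
    starts = [
        np.concatenate([base, [logit(rho0), np.log(0.1)]]),
        np.concatenate([base, [logit(0.1), np.log(0.3)]]),
        np.concatenate([base, [logit(0.005), np.log(0.01)]]),
    ]
    bounds = [(-30.0, 30.0)] * k + [
        (logit(1e-8), logit(0.95)),
        (np.log(_SU_MIN), np.log(5.0)),
    ]
    best = None
    for s0 in starts:
        nll._u = np.zeros(nll.J)
        try:
            res = minimize(
                fun, s0, method="L-BFGS-B", bounds=bounds,
                # eps well above the inner-solve noise floor of the
                # Laplace objective; the default step yields garbage
                # gradients near the optimum
                options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-8,
                         "eps": 1e-5},
            )
        except (ValueError, FloatingPointError):
            continue
        if best is None or res.fun < best.fun:
            best = res
        if res.success and best.fun < 1e11:
            break
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        return None, np.inf, None, False
    theta = best.x
    # Wald covariance from the coefficient block of the observed
    # information, with the nuisance parameters (rho, sigma_u) held at
    # their estimates: their curvature directions are nearly orthogonal
    # to the coefficients but numerically fragile near the boundary
    def fun_beta(tb):
        th = theta.copy()
        th[:k] = tb
        return fun(th)
    H = _numeric_hessian(fun_beta, theta[:k])
    cov = np.full((len(theta), len(theta)), np.nan)
    try:
        cov_b = np.linalg.pinv((H + H.T) / 2.0, rcond=1e-10, hermitian=True)
        if np.all(np.diag(cov_b) > 0):
            cov[:k, :k] = cov_b
        else:
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    return theta, best.fun, cov, True


def fit_bb_glmm(
    minor,
    coverage,
    design: pd.DataFrame,
    method: str = "laplace",
    quad_nodes: int = 15,
    center_generation: bool = True,
) -> BbFitResult:
    """Fit the beta-binomial GLMM at one locus.

    ``design`` needs columns T (0/1 trajectory), G (numeric generation)
    and rep (replicate-population label).  The generation variable is
    centered internally for numerical stability; estimates are reported
    on the original scale.  Optimizer failure yields ``converged=False``
    rather than an exception.
    """
    y = np.asarray(minor, dtype=float)
    n = np.asarray(coverage, dtype=float)
    nan4 = np.full(4, np.nan)
    if np.all(y == 0) or np.all(y == n):
        return BbFitResult(nan4, nan4, nan4, np.nan, np.nan, np.nan,
                           False, "no variation")
    g_mean = float(design["G"].mean()) if center_generation else 0.0
    g_scale = float(design["G"].std(ddof=0)) if center_generation else 1.0
    if not g_scale > 0:
        g_scale = 1.0
    d = design.copy()
    d["G"] = (d["G"] - g_mean) / g_scale
    X = _design_matrix(d)
    rep_idx = _rep_index(d)
    theta, fval, cov, ok = _fit_bb_mixed(
        y, n, X, rep_idx, method=method, quad_nodes=quad_nodes
    )
    if not ok:
        return BbFitResult(nan4, nan4, nan4, np.nan, np.nan, np.nan,
                           False, "optimizer failure")
    beta_c = theta[:4]
    rho = float(expit(theta[4]))
    su = float(np.exp(theta[5]))
    # undo the internal standardization of G (linear map on coefficients)
    A = np.eye(4)
    A[0, 2] = -g_mean / g_scale
    A[1, 3] = -g_mean / g_scale
    A[2, 2] = 1.0 / g_scale
    A[3, 3] = 1.0 / g_scale
    beta = A @ beta_c
    se = np.full(4, np.nan)
    if cov is not None:
        cb = A @ cov[:4, :4] @ A.T
        diag = np.diag(cb)
        if np.all(np.isfinite(diag)) and np.all(diag >= 0):
            se = np.sqrt(diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    if su <= _SU_MIN * 1.01:
        su = 0.0  # variance at the boundary: fixed-effects beta-binomial
    return BbFitResult(beta, se, p, rho, su * su, -fval, True)


def lrt_pvalues(minor, coverage, design: pd.DataFrame) -> np.ndarray:
    """Likelihood-ratio p-values for (treatment, generation, interaction),
    each against the model with that column dropped.  Validation mode for
    the default Wald tests."""
    y = np.asarray(minor, dtype=float)
    n = np.asarray(coverage, dtype=float)
    d = design.copy()
    s = d["G"].std(ddof=0) or 1.0
    d["G"] = (d["G"] - d["G"].mean()) / s
    X = _design_matrix(d)
    rep_idx = _rep_index(d)
    _, f_full, _, ok = _fit_bb_mixed(y, n, X, rep_idx)
    out = np.full(3, np.nan)
    if not ok:
        return out
    for i, col in enumerate((1, 2, 3)):
        Xr = np.delete(X, col, axis=1)
        _, f_red, _, okr = _fit_bb_mixed(y, n, Xr, rep_idx)
        if okr:
            stat = max(0.0, 2.0 * (f_red - f_full))
            out[i] = chi2.sf(stat, df=1)
    return out


@dataclass
class ScanResult:
    """Genome-wide scan output.

    ``frame`` has one row per tested locus with estimates, SEs, raw and
    Bonferroni-adjusted p-values per term, phi, sigma_u2, and boolean
    significance flags at ``alpha``.
    """

    frame: pd.DataFrame
    alpha: float
    n_tested: int

    def class_counts(self) -> dict:
        """Exclusive significance-class tallies (UpSet-style) over the
        treatment/generation/interaction flags."""
        flags = self.frame[["sig_treatment", "sig_generation", "sig_interaction"]]
        names = ("treatment", "generation", "interaction")
        counts: dict[tuple, int] = {}
        for combo in flags.itertuples(index=False):
            key = tuple(n for n, f in zip(names, combo) if f)
            if key:
                counts[key] = counts.get(key, 0) + 1
        return counts

    def significant_loci(self, term: str = "interaction") -> np.ndarray:
        return self.frame.index[self.frame[f"sig_{term}"]].to_numpy()


def trajectory_design(table: SnpTable) -> pd.DataFrame:
    """Build the scan design from trajectory samples (founders excluded)."""
    rows = []
    for j, s in enumerate(table.samples):
        if s.group in ("A2C", "C2A"):
            rows.append(
                {
                    "col": j,
                    "T": 0 if s.group == "A2C" else 1,
                    "G": s.generation,
                    "rep": f"{s.group}_{s.replicate}",
                }
            )
    if not rows:
        raise ValueError("table contains no trajectory samples")
    return pd.DataFrame(rows)


def scan_genome(
    table: SnpTable,
    design: pd.DataFrame | None = None,
    alpha: float = 0.05,
    method: str = "laplace",
    count_failures_in_m: bool = True,
) -> ScanResult:
    """Fit the beta-binomial GLMM at every locus and Bonferroni-adjust
    each term across tested loci.  Per-locus failures are recorded with
    NaN p-values; by default they still count in the multiplicity
    denominator."""
    if design is None:
        design = trajectory_design(table)
    cols = design["col"].to_numpy() if "col" in design else np.arange(table.n_samples)
    minor = table.minor[:, cols]
    cov = table.coverage[:, cols]
    recs = []
    for i in range(table.n_loci):
        fit = fit_bb_glmm(minor[i], cov[i], design, method=method)
        loc = table.loci[i]
        recs.append(
            {
                "chrom": loc.chrom, "pos": loc.pos,
                "b0": fit.beta[0], "b_treatment": fit.beta[1],
                "b_generation": fit.beta[2], "b_interaction": fit.beta[3],
                "se_treatment": fit.se[1], "se_generation": fit.se[2],
                "se_interaction": fit.se[3],
                "p_treatment": fit.p[1], "p_generation": fit.p[2],
                "p_interaction": fit.p[3],
                "phi": fit.phi, "sigma_u2": fit.sigma_u2,
                "loglik": fit.loglik, "converged": fit.converged,
            }
        )
    frame = pd.DataFrame(recs)
    n_fail = int((~frame["converged"]).sum())
    if n_fail:
        logger.info("scan_genome: %d loci failed to converge", n_fail)
    m = len(frame) if count_failures_in_m else int(frame["converged"].sum())
    for term in ("treatment", "generation", "interaction"):
        adj = np.minimum(1.0, frame[f"p_{term}"] * m)
        frame[f"padj_{term}"] = adj
        frame[f"sig_{term}"] = adj < alpha
    return ScanResult(frame=frame, alpha=alpha, n_tested=m)
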