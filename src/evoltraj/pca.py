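"""PCA of SNP frequency matrices and per-PC mixed-model trajectory tests.

Frequencies (with a pseudocount applied so no cell is 0 or 1) are scaled
to unit variance but *not* centered, then decomposed by SVD with samples
as observations.  Because the matrix is uncentered, the first component
typically absorbs the overall frequency profile shared by all samples;
trajectory structure shows up in the leading components' scores.

Each leading PC is then modelled as

    PC ~ trajectory * generation + (1 | population)

and the trajectory x generation interaction — opposite time trends in the
two reciprocal regimes — is tested per PC with Bonferroni adjustment
across PCs and model terms.  An endpoint mode drops generation and fits
ordinary linear models of score on group identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: np.ndarray             # samples x components
    variance_explained: np.ndarray  # non-increasing fractions summing to 1
    loadings: np.ndarray           # kept-loci x components
    kept_loci: np.ndarray          # indices of loci with nonzero variance


def run_pca(freq, sample_groups=None) -> PcaResult:
    """Scaled-uncentered PCA of a loci x samples frequency matrix.

    Each locus is divided by its standard deviation across samples
    (zero-variance loci are dropped with a log message); no mean is
    subtracted.  Scores are U·S from the SVD of the samples x loci
    matrix; ``variance_explained`` comes from the squared singular
    values.  If ``sample_groups`` labels are given and contain both
    founder groups, each component's sign is fixed so the mean
    FOUNDER_A score does not exceed the mean FOUNDER_C score.
    """
    F = np.asarray(freq, dtype=float).T  # samples x loci
    if F.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    sd = F.std(axis=0, ddof=1)
    keep = sd > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("run_pca: dropped %d zero-variance loci", n_drop)
    kept = np.flatnonzero(keep)
    M = F[:, keep] / sd[keep]
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    scores = U * S
    ve = S**2 / np.sum(S**2)
    loadings = Vt.T
    if sample_groups is not None:
        g = np.asarray(sample_groups)
        fa, fc = g == "FOUNDER_A", g == "FOUNDER_C"
        if fa.any() and fc.any():
            flip = scores[fa].mean(axis=0) > scores[fc].mean(axis=0)
            scores[:, flip] *= -1.0
            loadings[:, flip] *= -1.0
    return PcaResult(scores, ve, loadings, kept)


@dataclass
class PcLmmResult:
    """Per-PC mixed-model tests of trajectory, generation, and their
    interaction; ``frame`` has one row per (PC, term)."""

    frame: pd.DataFrame
    alpha: float
    method: str


def fit_pc_lmm(
    scores, design: pd.DataFrame, n_pcs: int = 10, alpha: float = 0.005
) -> PcLmmResult:
    """Linear mixed model per PC: score ~ T * G with a random intercept
    per population (REML, Wald z p-values); Bonferroni across PCs x terms.

    ``design`` rows correspond to rows of ``scores`` and need columns
    T (0/1 trajectory), G (generation), and population.  Inestimable or
    singular fits are flagged per PC, not fatal.
    """
    scores = np.asarray(scores, dtype=float)
    n_pcs = min(n_pcs, scores.shape[1])
    d = design.reset_index(drop=True).copy()
    counts = d.groupby("population")["G"].nunique()
    if (counts < 2).any():
        logger.warning("fit_pc_lmm: some populations have < 2 timepoints")
    rows = []
    single_traj = d["T"].nunique() < 2
    for c in range(n_pcs):
        d["score"] = scores[:, c]
        if single_traj:
            for term in ("T", "G", "T:G"):
                rows.append(
                    {"pc": c + 1, "term": term, "estimate": np.nan,
                     "p": np.nan, "flag": "single trajectory: inestimable"}
                )
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm("score ~ T * G", d, groups=d["population"])
                fit = model.fit(reml=True)
            flag = "" if fit.converged else "no convergence"
            for term_label, name in (("T", "T"), ("G", "G"), ("T:G", "T:G")):
                rows.append(
                    {"pc": c + 1, "term": term_label,
                     "estimate": float(fit.params.get(name, np.nan)),
                     "p": float(fit.pvalues.get(name, np.nan)),
                     "flag": flag}
                )
        except (np.linalg.LinAlgError, ValueError) as exc:
            for term in ("T", "G", "T:G"):
                rows.append(
                    {"pc": c + 1, "term": term, "estimate": np.nan,
                     "p": np.nan, "flag": f"singular fit: {exc}"}
                )
    frame = pd.DataFrame(rows)
    m = frame["p"].notna().sum()
    frame["padj"] = np.minimum(1.0, frame["p"] * max(m, 1))
    frame["sig"] = frame["padj"] < alpha
    return PcLmmResult(frame=frame, alpha=alpha, method="wald-z-mixedlm-reml")


def fit_endpoint_group_lm(
    scores, groups, n_pcs: int = 10, alpha: float = 0.005
) -> PcLmmResult:
    """Endpoint mode: ordinary linear model of each PC score on group
    identity (generation dropped); reports the model F-test per PC and
    the leading group contrast, Bonferroni-adjusted across PCs."""
    scores = np.asarray(scores, dtype=float)
    n_pcs = min(n_pcs, scores.shape[1])
    g = pd.Categorical(np.asarray(groups))
    X = pd.get_dummies(pd.Series(g), drop_first=True, dtype=float)
    X = sm.add_constant(X)
    rows = []
    for c in range(n_pcs):
        fit = sm.OLS(scores[:, c], X).fit()
        contrast = fit.params.iloc[1] if len(fit.params) > 1 else np.nan
        rows.append(
            {"pc": c + 1, "term": "group", "estimate": float(contrast),
             "p": float(fit.f_pvalue), "flag": ""}
        )
    frame = pd.DataFrame(rows)
    frame["padj"] = np.minimum(1.0, frame["p"] * len(frame))
    frame["sig"] = frame["padj"] < alpha
    return PcLmmResult(frame=frame, alpha=alpha, method="ols-group-f")
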