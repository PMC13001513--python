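"""Convergence of newly derived populations on founder genomic states.

For each SNP, minor-allele counts from the evolved endpoint populations
of one trajectory and the founder populations of the *target* regime
(C->A vs founder A, or A->C vs founder C) are modelled as overdispersed
binomial draws, and the population-type effect is tested by comparing
models with and without it.  Few significant loci means the evolved
replicates have converged on the founder allele-frequency state.

The default test is a quasi-likelihood F-test: the scaled deviance drop
for the population-type term divided by the Pearson dispersion of the
full model, referred to F(1, df_resid).  Replicate-to-replicate variation
is absorbed into the dispersion.  A beta-binomial likelihood-ratio mode
with an explicit replicate random intercept is available for sensitivity
analysis.  Chromosome 4 and globally monomorphic sites are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, f as f_dist

from .bb_scan import _fit_bb_mixed
from .glm import fit_binomial_many
from .snp_io import SnpTable

CONTRASTS = {
    "C2A-vs-FOUNDER_A": ("C2A", "FOUNDER_A"),
    "A2C-vs-FOUNDER_C": ("A2C", "FOUNDER_C"),
}


@dataclass
class ConvergenceResult:
    """Per-locus differentiation tests for one contrast.

    ``frame`` columns: chrom, pos, estimate (population-type effect on
    the logit scale), statistic, p, padj (Bonferroni), differentiated
    (padj < alpha), ok.
    """

    frame: pd.DataFrame
    contrast: str
    alpha: float
    method: str

    @property
    def n_differentiated(self) -> int:
        return int(self.frame["differentiated"].sum())


def convergence_scan(
    table: SnpTable,
    contrast: str,
    alpha: float = 0.05,
    method: str = "quasi-f",
    endpoint_only: bool = True,
) -> ConvergenceResult:
    """Test every locus for differentiation between evolved and founder
    populations of the same regime.

    ``contrast`` is one of ``C2A-vs-FOUNDER_A`` / ``A2C-vs-FOUNDER_C``.
    With ``endpoint_only`` the evolved group is restricted to its last
    sampled generation.  Chromosome 4 and sites monomorphic across all
    included samples are excluded from testing.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; use one of {list(CONTRASTS)}")
    evolved, founder = CONTRASTS[contrast]
    groups = [s.group for s in table.samples]
    for g in (evolved, founder):
        if g not in groups:
            raise ValueError(f"group {g!r} absent from table")
    sub = table.select_samples(group={evolved, founder})
    if endpoint_only:
        gens = [s.generation for s in sub.samples if s.group == evolved]
        keep = [
            j for j, s in enumerate(sub.samples)
            if s.group == founder or s.generation == max(gens)
        ]
        sub = sub.subset_samples(np.asarray(keep, dtype=int))
    n_ev = sum(1 for s in sub.samples if s.group == evolved)
    n_fo = sub.n_samples - n_ev
    if n_ev < 2 or n_fo < 2:
        raise ValueError("need >= 2 replicates in each group")

    not4 = np.array([l.chrom != "4" for l in sub.loci])
    poly = (sub.minor.sum(axis=1) > 0) & (sub.minor.sum(axis=1) < sub.coverage.sum(axis=1))
    tested = sub.subset_loci(not4 & poly)

    is_evolved = np.array([s.group == evolved for s in tested.samples], dtype=float)
    X_full = np.column_stack([np.ones_like(is_evolved), is_evolved])
    X_null = X_full[:, :1]

    if method == "quasi-f":
        full = fit_binomial_many(tested.minor, tested.coverage, X_full)
        null = fit_binomial_many(tested.minor, tested.coverage, X_null)
        df_resid = full["df_resid"]
        disp = np.maximum(full["pearson"] / df_resid, 1e-8)
        stat = (null["deviance"] - full["deviance"]) / disp
        stat = np.maximum(stat, 0.0)
        p = f_dist.sf(stat, 1, df_resid)
        est = full["coef"][:, 1]
        ok = full["ok"] & null["ok"]
    elif method == "betabinom-lrt":
        reps = np.array(
            [f"{s.group}_{s.replicate}" for s in tested.samples]
        )
        _, rep_idx = np.unique(reps, return_inverse=True)
        est = np.full(tested.n_loci, np.nan)
        stat = np.full(tested.n_loci, np.nan)
        p = np.full(tested.n_loci, np.nan)
        ok = np.zeros(tested.n_loci, dtype=bool)
        for i in range(tested.n_loci):
            y = tested.minor[i].astype(float)
            n = tested.coverage[i].astype(float)
            th_f, f_full, _, ok_f = _fit_bb_mixed(y, n, X_full, rep_idx)
            th_n, f_null, _, ok_n = _fit_bb_mixed(y, n, X_null, rep_idx)
            if ok_f and ok_n:
                est[i] = th_f[1]
                stat[i] = max(0.0, 2.0 * (f_null - f_full))
                p[i] = chi2.sf(stat[i], df=1)
                ok[i] = True
    else:
        raise ValueError(f"unknown method {method!r}")

    p = np.where(ok, p, np.nan)
    m = len(p)
    padj = np.minimum(1.0, p * m)
    frame = tested.loci_frame()[["chrom", "pos"]].copy()
    frame["estimate"] = est
    frame["statistic"] = stat
    frame["p"] = p
    frame["padj"] = padj
    frame["differentiated"] = padj < alpha
    frame["ok"] = ok
    return ConvergenceResult(frame=frame, contrast=contrast, alpha=alpha, method=method)
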