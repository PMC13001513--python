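"""Baseline quasibinomial scans and leave-one-out (LOO) parallelism.

For one trajectory, the baseline scan regresses minor/major counts on
numeric generation with replicate fixed effects under a quasibinomial
GLM, and Benjamini-Hochberg adjusts the generation p-values across loci.

The LOO framework asks whether the scan signal is replicate-independent:
each replicate in turn is held out, "target" SNPs are defined from the
remaining training replicates (BH-adjusted p below an FDR threshold and,
optionally, a minimum pooled |delta p|), and allele-frequency change is
then measured in the held-out replicate alone, at targets and at an
equal-sized random sample of non-target control SNPs.  Per-replicate
median delta p of targets versus controls, genome-wide and per
chromosome arm, is compared with two-sample two-tailed t-tests treating
replicates as independent units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist, ttest_ind
from statsmodels.stats.multitest import multipletests

from .glm import fit_binomial_many
from .snp_io import SnpTable

logger = logging.getLogger(__name__)

ARMS = ("2L", "2R", "3L", "3R", "X")


@dataclass
class TargetCriteria:
    """Thresholds defining target SNPs in a training set."""

    fdr_threshold: float = 0.05
    min_abs_dp: float = 0.02
    alt_fdr: float | None = None   # optional stricter threshold (e.g. 0.01)
    effect_filter_on: bool = True

    def __post_init__(self) -> None:
        for thr in (self.fdr_threshold, self.alt_fdr):
            if thr is not None and not 0.0 < thr < 1.0:
                raise ValueError(f"FDR threshold {thr} outside (0, 1)")
        if not 0.0 <= self.min_abs_dp <= 1.0:
            raise ValueError("min_abs_dp must lie in [0, 1]")


def _trajectory_table(table: SnpTable, trajectory: str | None) -> SnpTable:
    if trajectory is not None:
        table = table.select_samples(group=trajectory)
    groups = {s.group for s in table.samples}
    if len(groups) != 1 or not groups <= {"A2C", "C2A"}:
        raise ValueError("qb scans operate on a single trajectory's samples")
    return table


def qb_generation_scan(table: SnpTable, trajectory: str | None = None) -> pd.DataFrame:
    """Quasibinomial GLM per locus: counts ~ generation + replicate.

    Replicate enters as fixed-effect intercepts; the dispersion comes
    from Pearson residuals and the generation coefficient is tested with
    a t-statistic on the residual degrees of freedom.  Returns a frame
    with estimate, p, p_bh (BH across estimable loci), and ok.
    """
    sub = _trajectory_table(table, trajectory)
    gens = np.array([s.generation for s in sub.samples], dtype=float)
    reps = np.array([s.replicate for s in sub.samples])
    if len(np.unique(gens)) < 2:
        raise ValueError("need >= 2 generations")
    rep_ids = np.unique(reps)
    if len(rep_ids) < 2:
        raise ValueError("need >= 2 replicates")
    rep_dummies = (reps[:, None] == rep_ids[None, 1:]).astype(float)
    X = np.column_stack([np.ones_like(gens), gens, rep_dummies])
    res = fit_binomial_many(sub.minor, sub.coverage, X)
    df_resid = res["df_resid"]
    disp = np.maximum(res["pearson"] / df_resid, 1e-8)
    est = res["coef"][:, 1]
    se = np.sqrt(disp * res["cov_unscaled"][:, 1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = est / se
    p = 2.0 * t_dist.sf(np.abs(tval), df_resid)
    ok = res["ok"] & np.isfinite(p)
    p_bh = np.full(len(p), np.nan)
    if ok.any():
        p_bh[ok] = multipletests(p[ok], method="fdr_bh")[1]
    frame = sub.loci_frame()[["chrom", "pos"]].copy()
    frame["estimate"] = est
    frame["p"] = np.where(ok, p, np.nan)
    frame["p_bh"] = p_bh
    frame["ok"] = ok
    return frame


def delta_p(table: SnpTable, replicate_subset, loci=None) -> np.ndarray:
    """Net minor-allele frequency change, first to last sampled generation.

    Counts are pooled across the replicates in ``replicate_subset``
    within each generation: delta p = sum(minor)/sum(cov) at the last
    generation minus the same at the first.  Returns one value per locus
    (or per requested locus index).
    """
    reps = set(replicate_subset)
    gens = np.array([s.generation for s in table.samples], dtype=float)
    in_reps = np.array([s.replicate in reps for s in table.samples])
    avail = np.unique(gens[in_reps])
    if len(avail) < 2:
        raise ValueError("replicate subset spans fewer than 2 generations")
    g_first, g_last = avail[0], avail[-1]
    out = np.zeros(table.n_loci)
    for g, sign in ((g_first, -1.0), (g_last, +1.0)):
        cols = in_reps & (gens == g)
        if not cols.any():
            raise ValueError(f"generation {g} missing for the subset")
        mi = table.minor[:, cols].sum(axis=1).astype(float)
        cv = table.coverage[:, cols].sum(axis=1).astype(float)
        out += sign * np.divide(mi, cv, out=np.zeros_like(mi), where=cv > 0)
    if loci is not None:
        return out[np.asarray(loci)]
    return out


@dataclass
class LooSummary:
    """LOO results for one trajectory.

    ``per_iteration``: one row per held-out replicate x region with the
    target/control median delta p and target count (NaN medians when an
    iteration produced no targets).  ``tests``: per-region two-sample
    two-tailed t-test of replicate-level target vs control medians.
    Genome-wide medians pool loci across arms; arm rows are reported
    separately.
    """

    trajectory: str
    criteria: TargetCriteria
    per_iteration: pd.DataFrame
    tests: pd.DataFrame
    seed: int


def loo_parallelism(
    table: SnpTable,
    criteria: TargetCriteria | None = None,
    seed: int = 0,
    trajectory: str | None = None,
) -> LooSummary:
    """Leave-one-out parallelism analysis of one trajectory.

    For each held-out replicate: rerun the quasibinomial generation scan
    on the training replicates, define targets by the criteria (BH p <
    fdr and, if enabled, pooled training |delta p| >= min_abs_dp), draw
    an equal-sized control set uniformly without replacement from
    estimable non-target loci, and record the held-out replicate's own
    delta p medians at both sets, genome-wide and per chromosome arm.
    Control draws derive from ``seed`` and are independent across
    iterations.
    """
    if criteria is None:
        criteria = TargetCriteria()
    sub = _trajectory_table(table, trajectory)
    traj = sub.samples[0].group
    reps = sorted({s.replicate for s in sub.samples})
    if len(reps) < 3:
        raise ValueError("LOO needs >= 3 replicates")
    chroms = np.array([l.chrom for l in sub.loci])
    child_seeds = np.random.SeedSequence(seed).spawn(len(reps))

    fdr = criteria.alt_fdr if criteria.alt_fdr is not None else criteria.fdr_threshold
    rows = []
    for r_i, held in enumerate(reps):
        training = [r for r in reps if r != held]
        train_tab = sub.select_samples(replicate=set(training))
        scan = qb_generation_scan(train_tab)
        ok = scan["ok"].to_numpy()
        is_target = ok & (scan["p_bh"].to_numpy() < fdr)
        if criteria.effect_filter_on:
            dp_train = delta_p(train_tab, training)
            is_target &= np.abs(dp_train) >= criteria.min_abs_dp
        targets = np.flatnonzero(is_target)
        eligible = np.flatnonzero(ok & ~is_target)
        rng = np.random.default_rng(child_seeds[r_i])
        dp_held = delta_p(sub.select_samples(replicate=held), [held])
        if len(targets) == 0 or len(eligible) < len(targets):
            logger.warning(
                "loo_parallelism: replicate %s produced no usable target/"
                "control sets; iteration recorded empty", held
            )
            for region in ("genome",) + ARMS:
                rows.append(
                    {"replicate": held, "region": region, "n_targets": 0,
                     "target_median": np.nan, "control_median": np.nan}
                )
            continue
        controls = rng.choice(eligible, size=len(targets), replace=False)
        for region in ("genome",) + ARMS:
            if region == "genome":
                t_set, c_set = targets, controls
            else:
                t_set = targets[chroms[targets] == region]
                c_set = controls[chroms[controls] == region]
            rows.append(
                {
                    "replicate": held,
                    "region": region,
                    "n_targets": len(t_set),
                    "target_median": float(np.median(dp_held[t_set]))
                    if len(t_set) else np.nan,
                    "control_median": float(np.median(dp_held[c_set]))
                    if len(c_set) else np.nan,
                }
            )
    per_iter = pd.DataFrame(rows)

    tests = []
    for region in ("genome",) + ARMS:
        d = per_iter[(per_iter["region"] == region)
                     & per_iter["target_median"].notna()
                     & per_iter["control_median"].notna()]
        if len(d) < 2:
            tests.append({"region": region, "n_iterations": len(d),
                          "statistic": np.nan, "p": np.nan})
            continue
        t, p = ttest_ind(d["target_median"], d["control_median"])
        tests.append({"region": region, "n_iterations": len(d),
                      "statistic": float(t), "p": float(p)})
    return LooSummary(
        trajectory=traj,
        criteria=criteria,
        per_iteration=per_iter,
        tests=pd.DataFrame(tests),
        seed=int(seed),
    )
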