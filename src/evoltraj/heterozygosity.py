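"""Genome-wide expected heterozygosity and its trajectory over time.

Expected heterozygosity at a site is H = 2 f (1 - f) with f the
minor-allele frequency computed from raw counts (no pseudocount, so a
site sampled invariant contributes exactly 0).  Per-sample genome-wide
means are averaged over loci, and founder-vs-endpoint change within each
trajectory is tested with a Welch two-sample t-test on replicate means,
treating replicate populations as independent units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snp_io import SnpTable

logger = logging.getLogger(__name__)


def site_het(minor, coverage) -> np.ndarray:
    """H = 2 f (1 - f), f = minor / coverage; errors on zero coverage."""
    minor = np.asarray(minor, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if np.any(coverage <= 0):
        bad = np.argwhere(np.atleast_1d(coverage) <= 0)[:10]
        raise ValueError(f"site_het undefined at zero-coverage cells {bad.tolist()}")
    f = minor / coverage
    return 2.0 * f * (1.0 - f)


def _welch(x, y):
    """Welch t-test that treats a zero mean difference with zero variance
    as 'no change' (t = 0, p = 1) instead of NaN."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = y.mean() - x.mean()
    vx = x.var(ddof=1) / len(x) if len(x) > 1 else 0.0
    vy = y.var(ddof=1) / len(y) if len(y) > 1 else 0.0
    se2 = vx + vy
    if se2 == 0.0:
        return (0.0, 1.0) if d == 0.0 else (np.sign(d) * np.inf, 0.0)
    t = d / np.sqrt(se2)
    df = se2**2 / (
        (vx**2 / (len(x) - 1) if len(x) > 1 else 0.0)
        + (vy**2 / (len(y) - 1) if len(y) > 1 else 0.0)
    )
    from scipy.stats import t as t_dist

    return float(t), float(2.0 * t_dist.sf(abs(t), df))


@dataclass
class HetSummary:
    """Per-sample mean heterozygosity plus first-vs-last generation tests.

    ``per_sample`` has one row per sample (sample_id, group, replicate,
    generation, mean_het); ``tests`` one row per trajectory with the
    Welch t statistic, p-value, and direction of change (+1/-1/0).
    """

    per_sample: pd.DataFrame
    tests: pd.DataFrame


def het_trend(table: SnpTable) -> HetSummary:
    """Mean heterozygosity per sample and its first-to-last generation
    change within each trajectory present in the table."""
    H = site_het(table.minor, table.coverage)
    per = table.samples_frame()
    per["mean_het"] = H.mean(axis=0)

    rows = []
    for traj in ("A2C", "C2A"):
        sub = per[per["group"] == traj]
        if sub.empty:
            continue
        gens = np.sort(sub["generation"].unique())
        if len(gens) < 2:
            raise ValueError(f"trajectory {traj} needs >= 2 generations")
        first = sub[sub["generation"] == gens[0]].sort_values("replicate")
        last = sub[sub["generation"] == gens[-1]].sort_values("replicate")
        if len(first) < 2 or len(last) < 2:
            logger.warning("het_trend: single replicate in %s; test skipped", traj)
            rows.append(
                {"trajectory": traj, "gen_first": gens[0], "gen_last": gens[-1],
                 "statistic": np.nan, "p": np.nan, "direction": 0}
            )
            continue
        t, p = _welch(first["mean_het"].to_numpy(), last["mean_het"].to_numpy())
        diff = last["mean_het"].mean() - first["mean_het"].mean()
        rows.append(
            {"trajectory": traj, "gen_first": gens[0], "gen_last": gens[-1],
             "statistic": t, "p": p, "direction": int(np.sign(diff))}
        )
    return HetSummary(per_sample=per, tests=pd.DataFrame(rows))
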