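"""Pseudo-fixed sites and the hidden-variation permutation test.

A pseudo-fixed site is a scan-significant SNP whose minor-allele count in
a focal sample is 0 or equal to coverage at standard sequencing depth:
the site looks fixed, but may segregate at a frequency too low to sample
at ~90x.  Re-reading the same pool at high depth (~800x) recovers these
frequencies; the test asks whether the mean minor-allele frequency of the
pseudo-fixed set is lower than that of random, equal-sized SNP sets drawn
from the deep data (a permutation null), reported as a z-score and a
+1-smoothed one-sided empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .snp_io import SnpTable


def find_pseudo_fixed(
    table: SnpTable, focal_sample: str, significant_loci
) -> np.ndarray:
    """Indices of ``significant_loci`` that look fixed in ``focal_sample``
    (minor count 0, or equal to coverage) at standard depth."""
    j = table.sample_index(focal_sample)
    idx = np.asarray(list(significant_loci), dtype=int)
    if idx.size == 0:
        return idx
    m = table.minor[idx, j]
    c = table.coverage[idx, j]
    return idx[(m == 0) | (m == c)]


def folded_maf(table: SnpTable, sample: str | int = 0) -> np.ndarray:
    """Minor-allele frequency in one sample, folded to <= 0.5 so sites
    fixed for the globally-minor nucleotide contribute the frequency of
    their locally rare allele."""
    j = table.sample_index(sample) if isinstance(sample, str) else int(sample)
    f = table.minor[:, j] / table.coverage[:, j].astype(float)
    return np.minimum(f, 1.0 - f)


@dataclass
class PseudoFixedReport:
    """Permutation-test summary for the pseudo-fixed site set."""

    sites: np.ndarray          # locus indices of the tested set
    site_mafs: np.ndarray      # deep-coverage folded MAFs of the set
    observed_mean: float
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float         # (1 + #{null <= observed}) / (1 + n_perm)
    n_le: int                  # raw count of permuted means <= observed
    n_permutations: int
    seed: int


def permutation_test_mean_maf(
    pseudo_fixed_mafs,
    background_mafs,
    n_perm: int = 10000,
    seed: int = 0,
    sites=None,
) -> PseudoFixedReport:
    """Compare the mean MAF of the pseudo-fixed set against means of
    equal-sized random subsets drawn without replacement from the
    background.  The empirical p is the +1-smoothed proportion of
    permuted means <= the observed mean (one-sided: depletion)."""
    obs = np.asarray(pseudo_fixed_mafs, dtype=float)
    bg = np.asarray(background_mafs, dtype=float)
    k = len(obs)
    if k == 0:
        raise ValueError("pseudo-fixed set is empty")
    if len(bg) < k:
        raise ValueError(
            f"background ({len(bg)}) smaller than pseudo-fixed set ({k})"
        )
    rng = np.random.default_rng(seed)
    observed = float(obs.mean())
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = bg[rng.choice(len(bg), size=k, replace=False)].mean()
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=0))
    z = (observed - null_mean) / null_sd if null_sd > 0 else 0.0
    # tolerance so exact ties (e.g. set == background) count as <=
    n_le = int(np.sum(null <= observed + 1e-12))
    p = (1.0 + n_le) / (1.0 + n_perm)
    return PseudoFixedReport(
        sites=np.asarray(sites if sites is not None else np.arange(k)),
        site_mafs=obs,
        observed_mean=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_empirical=float(p),
        n_le=n_le,
        n_permutations=int(n_perm),
        seed=int(seed),
    )


def hidden_variation_report(
    standard: SnpTable,
    deep: SnpTable,
    focal_sample: str,
    significant_loci,
    deep_sample: str | int = 0,
    deep_min_cov: int = 1,
    n_perm: int = 10000,
    seed: int = 0,
) -> PseudoFixedReport:
    """End-to-end pseudo-fixed analysis.

    Finds pseudo-fixed sites among ``significant_loci`` in the standard-
    depth focal sample, intersects them with deep-coverage loci (matched
    by chromosome and position, coverage >= ``deep_min_cov``), and runs
    the permutation test against the full deep-coverage background.
    """
    pf = find_pseudo_fixed(standard, focal_sample, significant_loci)
    deep_key = {(l.chrom, l.pos): i for i, l in enumerate(deep.loci)}
    j = deep.sample_index(deep_sample) if isinstance(deep_sample, str) else int(deep_sample)
    cov_ok = deep.coverage[:, j] >= deep_min_cov
    mafs_all = np.minimum(
        deep.minor[:, j] / np.maximum(deep.coverage[:, j], 1).astype(float),
        1.0 - deep.minor[:, j] / np.maximum(deep.coverage[:, j], 1).astype(float),
    )
    pf_deep = []
    for i in pf:
        loc = standard.loci[i]
        di = deep_key.get((loc.chrom, loc.pos))
        if di is not None and cov_ok[di]:
            pf_deep.append((i, di))
    if not pf_deep:
        raise ValueError("no pseudo-fixed sites with deep coverage available")
    std_idx = np.array([i for i, _ in pf_deep])
    deep_idx = np.array([d for _, d in pf_deep])
    background = mafs_all[cov_ok]
    return permutation_test_mean_maf(
        mafs_all[deep_idx], background, n_perm=n_perm, seed=seed, sites=std_idx
    )
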