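"""Forward Wright–Fisher Pool-seq simulator for reciprocal selection shifts.

The generator emulates a pair of antiparallel selection trajectories
(A→C and C→A) derived from two sets of long-established founder
populations that share ancestral standing variation.  Three locus classes
are simulated, all evolving independently (free recombination, no linkage):

* ``neutral`` — drift only, shared ancestral frequency in both founder sets.
* ``directional`` — additive viability selection (favored homozygote
  fitness 1 + s) with the favored allele reversed between regimes, so the
  two trajectories move antiparallel from opposite founder states.
* ``balanced`` — heterozygote advantage whose internal equilibrium is
  regime-dependent: a low "hidden" equilibrium (0.005–0.02 by default)
  under early-reproduction (A-type) selection and a moderate equilibrium
  (0.30) under late-reproduction (C-type) selection.  Relaxing A-type
  selection therefore releases a reservoir of low-frequency alleles —
  the mechanism behind the heterozygosity rebound and the pseudo-fixed
  site analysis.

Observation follows the standard two-stage Pool-seq noise model: a pool
of ~200 diploid females is drawn binomially from the population frequency,
then reads are drawn binomially from the pool frequency at a Poisson
depth (truncated at 1).  Per-sample mean depths are drawn uniformly from
62–113×, matching typical Pool-seq studies of this design; a deep-
sequencing mode re-reads one founder pool at 800×.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .snp_io import CHROMOSOMES, Locus, SampleMeta, SnpTable

_MAJOR_ARMS = ("2L", "2R", "3L", "3R", "X")


@dataclass
class SimConfig:
    """Parameterization of one simulated reciprocal-shift experiment."""

    n_loci: int = 1000
    n_selected: int = 100
    n_balanced: int = 100
    pop_size: int = 1000              # diploid census N
    n_replicates: int = 10            # per trajectory (and per founder set)
    sampled_generations: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            "A2C": (12.0, 33.0, 65.0),
            "C2A": (33.0, 143.0, 182.0),
        }
    )
    s: float = 0.05                   # additive selection coefficient
    h_balance: float = 0.05           # common-homozygote penalty, C regime
    hidden_hom_penalty: float = 0.5   # hidden-homozygote penalty, A regime
    balanced_eq_c: float = 0.30       # balanced-locus equilibrium, C regime
    hidden_freq_range: tuple[float, float] = (0.005, 0.02)
    neutral_freq_range: tuple[float, float] = (0.05, 0.95)
    directional_founder_freq: tuple[float, float] = (0.85, 0.95)
    founder_burnin: int = 20          # drift generations per founder replicate
    pool_size: int = 200              # diploid individuals pooled per sample
    mean_coverage: float = 90.0       # used when coverage_range is None
    coverage_range: tuple[float, float] | None = (62.0, 113.0)
    deep_coverage: float = 800.0
    frac_chrom4: float = 0.02         # fraction of neutral loci on the dot
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_selected + self.n_balanced > self.n_loci:
            raise ValueError("n_selected + n_balanced must not exceed n_loci")
        if not 0 < self.s < 1:
            raise ValueError("s must lie in (0, 1)")
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if self.pool_size > self.pop_size:
            raise ValueError("pool_size cannot exceed pop_size")
        if not 0 < self.balanced_eq_c < 1:
            raise ValueError("balanced_eq_c must lie in (0, 1)")

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["sampled_generations"] = {
            k: [float(g) for g in v] for k, v in self.sampled_generations.items()
        }
        for k in (
            "hidden_freq_range", "neutral_freq_range",
            "directional_founder_freq", "coverage_range",
        ):
            if d[k] is not None:
                d[k] = [float(x) for x in d[k]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in (
            "hidden_freq_range", "neutral_freq_range",
            "directional_founder_freq", "coverage_range",
        ):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class TruthTable:
    """Per-locus ground truth for recovery tests.

    ``sign_a2c`` / ``sign_c2a`` give the expected direction of
    *minor-allele* frequency change in each trajectory (+1 up, −1 down,
    0 neutral); directional loci are antiparallel by construction.
    ``paths[trajectory][i, r, k]`` is the true minor-allele frequency at
    locus i, replicate r, sampled generation k; ``founder_freqs[group][i, r]``
    the post-burn-in founder frequency.
    """

    classes: np.ndarray
    sign_a2c: np.ndarray
    sign_c2a: np.ndarray
    sampled_generations: dict
    paths: dict
    founder_freqs: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": np.arange(len(self.classes)),
                "class": self.classes,
                "sign_A2C": self.sign_a2c,
                "sign_C2A": self.sign_c2a,
            }
        )


@dataclass
class SimResult:
    table: SnpTable
    truth: TruthTable
    deep: SnpTable  # one 800× re-read of FOUNDER_A replicate 1


# ---------------------------------------------------------------------------
# elementary steps
# ---------------------------------------------------------------------------

def selection_update(freq, w_AA, w_Aa, w_aa):
    """Deterministic viability-selection update of the A-allele frequency.

    f' = (f²·w_AA + f(1−f)·w_Aa) / (f²·w_AA + 2f(1−f)·w_Aa + (1−f)²·w_aa)
    """
    f = np.asarray(freq, dtype=float)
    num = f * f * w_AA + f * (1.0 - f) * w_Aa
    den = f * f * w_AA + 2.0 * f * (1.0 - f) * w_Aa + (1.0 - f) ** 2 * w_aa
    out = np.divide(num, den, out=np.zeros_like(f), where=den > 0)
    return out


def wright_fisher_step(freq, N, w_AA, w_Aa, w_aa, rng):
    """One generation: deterministic selection, then binomial drift at 2N."""
    if np.any(np.asarray(freq) < 0) or np.any(np.asarray(freq) > 1):
        raise ValueError("freq must lie in [0, 1]")
    for w in (w_AA, w_Aa, w_aa):
        if np.any(np.asarray(w) <= 0):
            raise ValueError("fitnesses must be positive")
    f_sel = selection_update(freq, w_AA, w_Aa, w_aa)
    return rng.binomial(2 * N, f_sel) / (2.0 * N)


def wright_fisher_trajectory(freq0, N, w_AA, w_Aa, w_aa, generations, rng):
    """Frequencies at the requested (integer) generations; generation 0 is
    the initial state.  Vectorized over loci."""
    gens = [int(g) for g in generations]
    if any(g < 0 for g in gens):
        raise ValueError("generations must be non-negative")
    horizon = max(gens) if gens else 0
    f = np.array(freq0, dtype=float, copy=True)
    out = np.empty((len(gens),) + f.shape)
    for k, g in enumerate(gens):
        if g == 0:
            out[k] = f
    for t in range(1, horizon + 1):
        f = wright_fisher_step(f, N, w_AA, w_Aa, w_aa, rng)
        for k, g in enumerate(gens):
            if g == t:
                out[k] = f
    return out


def _pool_freq(true_freq, pool_size, rng):
    return rng.binomial(2 * pool_size, true_freq) / (2.0 * pool_size)


def _read_counts(pool_q, depth_mean, rng):
    cov = np.maximum(1, rng.poisson(depth_mean, size=np.shape(pool_q)))
    minor = rng.binomial(cov, pool_q)
    return minor, cov


def pool_seq_sample(true_freq, pool_size, depth_mean, rng):
    """Two-stage Pool-seq draw: pool of individuals, then reads.

    Returns ``(minor_count, coverage)`` with coverage ~ Poisson truncated
    at 1.  The pool stage adds overdispersion relative to a plain binomial
    read draw at the population frequency.
    """
    f = np.asarray(true_freq, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("true_freq must lie in [0, 1]")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    q = _pool_freq(f, pool_size, rng)
    return _read_counts(q, depth_mean, rng)


# ---------------------------------------------------------------------------
# locus architecture
# ---------------------------------------------------------------------------

def _locus_fitnesses(config: SimConfig, hidden_eq: np.ndarray):
    """Tracked-allele fitness triples (w_tt, w_th, w_oo) per regime.

    Tracked allele: the A-favored allele at directional loci, the hidden
    (rare-under-A) allele at balanced loci.  Heterozygote-advantage
    equilibrium is q* = s_low / (s_low + s_high) with s_high the tracked-
    homozygote penalty and s_low the common-homozygote penalty.
    """
    n, nd, nb = config.n_loci, config.n_selected, config.n_balanced
    w = {
        "A": [np.ones(n), np.ones(n), np.ones(n)],
        "C": [np.ones(n), np.ones(n), np.ones(n)],
    }
    s = config.s
    d = slice(0, nd)
    w["A"][0][d] = 1.0 + s
    w["A"][1][d] = 1.0 + s / 2.0
    w["C"][1][d] = 1.0 + s / 2.0
    w["C"][2][d] = 1.0 + s
    b = slice(nd, nd + nb)
    # A regime: strong penalty on the hidden homozygote pins q* low.
    s_high_a = config.hidden_hom_penalty
    s_low_a = s_high_a * hidden_eq / (1.0 - hidden_eq)
    w["A"][0][b] = 1.0 - s_high_a
    w["A"][2][b] = 1.0 - s_low_a
    # C regime: moderate overdominance with equilibrium balanced_eq_c.
    s_low_c = config.h_balance
    s_high_c = s_low_c * (1.0 - config.balanced_eq_c) / config.balanced_eq_c
    w["C"][0][b] = 1.0 - s_high_c
    w["C"][2][b] = 1.0 - s_low_c
    return w


def _make_loci(config: SimConfig, rng) -> list[Locus]:
    classes = (["directional"] * config.n_selected
               + ["balanced"] * config.n_balanced
               + ["neutral"] * (config.n_loci - config.n_selected - config.n_balanced))
    loci = []
    counters = {c: 0 for c in CHROMOSOMES}
    n4 = int(round(config.frac_chrom4 * classes.count("neutral")))
    neutral_seen = 0
    for i, cls in enumerate(classes):
        if cls == "neutral" and neutral_seen < n4:
            chrom = "4"
            neutral_seen += 1
        else:
            chrom = _MAJOR_ARMS[i % len(_MAJOR_ARMS)]
        counters[chrom] += 1
        pos = counters[chrom] * 1000 + int(rng.integers(1, 1000))
        loci.append(Locus(chrom, pos, "T", "A"))  # labels fixed up later
    return loci


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------

def simulate_experiment(config: SimConfig) -> SimResult:
    """Simulate founders, trajectories, and Pool-seq observation.

    Fully reproducible from ``config.seed``.  Returns the combined
    standard-depth :class:`SnpTable` (founders plus trajectory samples),
    the :class:`TruthTable`, and a deep-coverage re-read of founder-A
    replicate 1 drawn from the same pool frequencies as its standard
    sample.
    """
    n = config.n_loci
    nd, nb = config.n_selected, config.n_balanced
    ss = np.random.SeedSequence(config.seed)
    (ss_init, ss_burn, ss_traj, ss_obs, ss_cov) = ss.spawn(5)
    rng_init = np.random.default_rng(ss_init)

    classes = np.array(
        ["directional"] * nd + ["balanced"] * nb + ["neutral"] * (n - nd - nb)
    )
    loci = _make_loci(config, rng_init)
    hidden_eq = rng_init.uniform(*config.hidden_freq_range, size=nb)
    fit = _locus_fitnesses(config, hidden_eq)

    # Tracked-allele founder base frequencies (pre-burn-in, shared ancestry).
    base = {"A": np.empty(n), "C": np.empty(n)}
    q_dir_a = rng_init.uniform(*config.directional_founder_freq, size=nd)
    base["A"][:nd] = q_dir_a
    base["C"][:nd] = 1.0 - q_dir_a  # reciprocal regime favors the other allele
    base["A"][nd:nd + nb] = hidden_eq
    base["C"][nd:nd + nb] = config.balanced_eq_c
    q_neutral = rng_init.uniform(*config.neutral_freq_range, size=n - nd - nb)
    base["A"][nd + nb:] = q_neutral
    base["C"][nd + nb:] = q_neutral

    R = config.n_replicates
    founder = {}  # regime -> (n_loci, R) tracked-allele freqs
    burn_rngs = [np.random.default_rng(s) for s in ss_burn.spawn(2 * R)]
    for gi, regime in enumerate(("A", "C")):
        w = fit[regime]
        cols = []
        for r in range(R):
            rng = burn_rngs[gi * R + r]
            f = base[regime].copy()
            for _ in range(config.founder_burnin):
                f = wright_fisher_step(f, config.pop_size, *w, rng)
            cols.append(f)
        founder[regime] = np.column_stack(cols)

    # Trajectories: replicate r of A2C descends from founder-A replicate r
    # and evolves under the C regime (and vice versa).
    traj_regime = {"A2C": "C", "C2A": "A"}
    paths = {}  # trajectory -> (n_loci, R, n_gens)
    traj_rngs = [np.random.default_rng(s) for s in ss_traj.spawn(2 * R)]
    for ti, traj in enumerate(("A2C", "C2A")):
        gens = [int(g) for g in config.sampled_generations[traj]]
        w = fit[traj_regime[traj]]
        arr = np.empty((n, R, len(gens)))
        src = "A" if traj == "A2C" else "C"
        for r in range(R):
            rng = traj_rngs[ti * R + r]
            out = wright_fisher_trajectory(
                founder[src][:, r], config.pop_size, *w, gens, rng
            )
            arr[:, r, :] = out.T
        paths[traj] = arr

    # --- Pool-seq observation -------------------------------------------
    sample_specs = []  # (meta, tracked_freq_vector)
    for r in range(R):
        sample_specs.append(
            (SampleMeta(f"FA{r + 1}", "FOUNDER_A", r + 1, 0.0, "T1"),
             founder["A"][:, r])
        )
    for r in range(R):
        sample_specs.append(
            (SampleMeta(f"FC{r + 1}", "FOUNDER_C", r + 1, 0.0, "T1"),
             founder["C"][:, r])
        )
    for traj in ("A2C", "C2A"):
        gens = list(config.sampled_generations[traj])
        for k, g in enumerate(gens):
            for r in range(R):
                sample_specs.append(
                    (SampleMeta(f"{traj}_{r + 1}_g{g:g}", traj, r + 1,
                                float(g), f"T{k + 2}"),
                     paths[traj][:, r, k])
                )

    rng_cov = np.random.default_rng(ss_cov)
    if config.coverage_range is not None:
        depth_means = rng_cov.uniform(*config.coverage_range, len(sample_specs))
    else:
        depth_means = np.full(len(sample_specs), config.mean_coverage)

    obs_rngs = [np.random.default_rng(s) for s in ss_obs.spawn(len(sample_specs) + 1)]
    tracked = np.empty((n, len(sample_specs)), dtype=np.int64)
    cov = np.empty((n, len(sample_specs)), dtype=np.int64)
    deep_tracked = deep_cov = None
    for j, (meta, f) in enumerate(sample_specs):
        rng = obs_rngs[j]
        q = _pool_freq(f, config.pool_size, rng)
        tracked[:, j], cov[:, j] = _read_counts(q, depth_means[j], rng)
        if meta.sample_id == "FA1":
            # deep re-read of the same pool (shared pool frequencies)
            deep_tracked, deep_cov = _read_counts(
                q, config.deep_coverage, obs_rngs[-1]
            )

    # --- global minor-allele convention ----------------------------------
    tracked_total = tracked.sum(axis=1)
    cov_total = cov.sum(axis=1)
    flip = tracked_total * 2 > cov_total  # tracked allele is the major one
    minor = np.where(flip[:, None], cov - tracked, tracked)
    loci = [
        Locus(l.chrom, l.pos, "A", "T") if fl else l
        for l, fl in zip(loci, flip)
    ]

    sign_a2c = np.zeros(n, dtype=int)
    sign_c2a = np.zeros(n, dtype=int)
    # tracked allele rises under the A regime at directional loci and is
    # held low there at balanced loci, so for the tracked allele:
    #   A2C (C regime): directional −1, balanced +1;  C2A (A regime): mirror.
    sign_a2c[:nd], sign_c2a[:nd] = -1, +1
    sign_a2c[nd:nd + nb], sign_c2a[nd:nd + nb] = +1, -1
    sgn = np.where(flip, -1, 1)
    sign_a2c *= sgn
    sign_c2a *= sgn
    minor_paths = {
        t: np.where(flip[:, None, None], 1.0 - p, p) for t, p in paths.items()
    }
    founder_minor = {
        f"FOUNDER_{g}": np.where(flip[:, None], 1.0 - founder[g], founder[g])
        for g in ("A", "C")
    }

    metas = [m for m, _ in sample_specs]
    table = SnpTable(loci, metas, minor, cov)
    deep_minor = np.where(flip, deep_cov - deep_tracked, deep_tracked)
    deep = SnpTable(
        list(loci),
        [SampleMeta("FA1_deep", "FOUNDER_A", 1, 0.0, "T1deep")],
        deep_minor[:, None],
        np.asarray(deep_cov)[:, None],
    )
    truth = TruthTable(
        classes=classes,
        sign_a2c=sign_a2c,
        sign_c2a=sign_c2a,
        sampled_generations={
            t: [float(g) for g in config.sampled_generations[t]]
            for t in ("A2C", "C2A")
        },
        paths=minor_paths,
        founder_freqs=founder_minor,
    )
    return SimResult(table=table, truth=truth, deep=deep)


# ---------------------------------------------------------------------------
# direct draws from the beta-binomial GLMM (for calibration studies)
# ---------------------------------------------------------------------------

def glmm_design(
    n_replicates: int = 10,
    generations: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Sample layout for GLMM simulations: one row per (trajectory,
    replicate, generation) with the treatment indicator T (0 = A→C,
    1 = C→A), numeric generation G, and a replicate-population label."""
    if generations is None:
        generations = {"A2C": (12.0, 33.0, 65.0), "C2A": (33.0, 143.0, 182.0)}
    rows = []
    for t_ind, traj in enumerate(("A2C", "C2A")):
        for r in range(1, n_replicates + 1):
            for g in generations[traj]:
                rows.append(
                    {"T": t_ind, "G": float(g), "rep": f"{traj}_{r}"}
                )
    return pd.DataFrame(rows)


def simulate_bb_counts(
    design: pd.DataFrame,
    beta: Sequence[float],
    rho: float,
    sigma_u: float,
    n_loci: int,
    mean_coverage: float = 90.0,
    rng: np.random.Generator | None = None,
):
    """Draw (minor, coverage) matrices straight from the beta-binomial
    GLMM: logit(p) = β0 + β1·T + β2·G + β3·T·G + u_rep, u ~ N(0, σ_u²),
    counts ~ BetaBinomial(n, p, ρ) with intraclass correlation ρ."""
    if rng is None:
        rng = np.random.default_rng()
    T = design["T"].to_numpy(float)
    G = design["G"].to_numpy(float)
    reps = design["rep"].to_numpy()
    rep_ids, rep_idx = np.unique(reps, return_inverse=True)
    beta = np.atleast_2d(np.asarray(beta, dtype=float))  # (1 or n_loci, 4)
    X = np.column_stack([np.ones_like(T), T, G, T * G])
    eta_fixed = beta @ X.T  # (1 or n_loci, n_samples)
    eta_fixed = np.broadcast_to(eta_fixed, (n_loci, len(T))).copy()
    u = rng.normal(0.0, sigma_u, size=(n_loci, len(rep_ids)))
    eta = eta_fixed + u[:, rep_idx]
    p = 1.0 / (1.0 + np.exp(-eta))
    cov = np.maximum(1, rng.poisson(mean_coverage, size=eta.shape))
    if rho > 0:
        a = p * (1.0 - rho) / rho
        b = (1.0 - p) * (1.0 - rho) / rho
        p_obs = rng.beta(a, b)
        minor = rng.binomial(cov, p_obs)
    else:
        minor = rng.binomial(cov, p)
    return minor.astype(np.int64), cov.astype(np.int64)
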