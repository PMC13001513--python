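"""Wright-Fisher dynamics, Pool-seq noise, and scenario construction."""

import numpy as np
import pytest

from evoltraj import (
    SimConfig,
    pool_seq_sample,
    simulate_experiment,
    wright_fisher_step,
    wright_fisher_trajectory,
)
from evoltraj.simulate import glmm_design, selection_update, simulate_bb_counts


class TestWrightFisherStep:
    def test_boundaries_absorbing(self):
        rng = np.random.default_rng(0)
        assert wright_fisher_step(0.0, 100, 1.1, 1.0, 1.0, rng) == 0.0
        assert wright_fisher_step(1.0, 100, 1.1, 1.0, 1.0, rng) == 1.0

    def test_neutral_update_is_unbiased(self):
        # equal fitnesses: deterministic part leaves f unchanged, drift
        # is mean-zero binomial sampling
        assert selection_update(0.3, 1.0, 1.0, 1.0) == pytest.approx(0.3)
        rng = np.random.default_rng(1)
        draws = wright_fisher_step(np.full(20000, 0.3), 500, 1.0, 1.0, 1.0, rng)
        assert draws.mean() == pytest.approx(0.3, abs=0.001)

    def test_symmetric_overdominance_equilibrium(self):
        assert selection_update(0.5, 0.9, 1.0, 0.9) == pytest.approx(0.5)

    def test_selection_update_closed_form(self):
        f, wAA, wAa, waa = 0.2, 1.05, 1.0, 0.95
        num = f * f * wAA + f * (1 - f) * wAa
        den = f * f * wAA + 2 * f * (1 - f) * wAa + (1 - f) ** 2 * waa
        assert selection_update(f, wAA, wAa, waa) == pytest.approx(num / den)

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            wright_fisher_step(1.2, 100, 1, 1, 1, rng)
        with pytest.raises(ValueError):
            wright_fisher_step(0.5, 100, 0.0, 1, 1, rng)


class TestPoolSeq:
    def test_absent_allele_never_observed(self):
        rng = np.random.default_rng(0)
        minor, cov = pool_seq_sample(np.zeros(1000), 200, 90, rng)
        assert minor.sum() == 0
        assert np.all(cov >= 1)

    def test_mean_frequency_unbiased(self):
        rng = np.random.default_rng(1)
        minor, cov = pool_seq_sample(np.full(100_000, 0.5), 200, 90, rng)
        assert (minor / cov).mean() == pytest.approx(0.5, abs=0.01)

    def test_pool_stage_adds_overdispersion(self):
        # two-stage variance exceeds single-binomial read sampling:
        # Var(f_hat) ~ pq/(2*pool) + pq/E[n] vs pq/E[n] alone
        rng = np.random.default_rng(2)
        minor, cov = pool_seq_sample(np.full(100_000, 0.5), 50, 90, rng)
        v = (minor / cov).var()
        v_binom = (rng.binomial(90, 0.5, 100_000) / 90).var()
        assert v > 1.5 * v_binom


class TestNeutralDrift:
    def test_variance_matches_closed_form(self):
        # Var(f_t) = f0(1-f0) * (1 - (1 - 1/2N)^t)
        f0, N, t = 0.3, 1000, 20
        rng = np.random.default_rng(3)
        out = wright_fisher_trajectory(
            np.full(4000, f0), N, 1.0, 1.0, 1.0, [t], rng
        )[0]
        expected = f0 * (1 - f0) * (1 - (1 - 1 / (2 * N)) ** t)
        assert out.mean() == pytest.approx(f0, abs=0.002)
        assert out.var() == pytest.approx(expected, rel=0.15)

    def test_het_decay_rate_near_1_over_2N(self):
        N = 200
        rng = np.random.default_rng(4)
        gens = list(range(0, 81, 10))
        out = wright_fisher_trajectory(
            np.full(3000, 0.5), N, 1.0, 1.0, 1.0, gens, rng
        )
        H = (2 * out * (1 - out)).mean(axis=1)
        rate = -np.polyfit(gens, np.log(H), 1)[0]
        assert rate == pytest.approx(1 / (2 * N), rel=0.2)


class TestDirectionalSelection:
    def test_favored_allele_rises_in_most_replicates(self):
        rng = np.random.default_rng(5)
        s = 0.05
        final = wright_fisher_trajectory(
            np.full(10, 0.5), 1000, 1 + s, 1 + s / 2, 1.0, [100], rng
        )[0]
        assert np.sum(final > 0.5) >= 9


class TestSimulateExperiment:
    def test_seed_reproducibility(self):
        cfg = SimConfig(n_loci=100, n_selected=20, n_balanced=20, seed=7)
        a = simulate_experiment(cfg)
        b = simulate_experiment(cfg)
        np.testing.assert_array_equal(a.table.minor, b.table.minor)
        np.testing.assert_array_equal(a.table.coverage, b.table.coverage)
        np.testing.assert_array_equal(a.deep.minor, b.deep.minor)
        for t in ("A2C", "C2A"):
            np.testing.assert_array_equal(a.truth.paths[t], b.truth.paths[t])

    def test_antiparallel_truth_signs(self, sim_default):
        tr = sim_default.truth
        d = tr.classes == "directional"
        b = tr.classes == "balanced"
        n = tr.classes == "neutral"
        assert np.all(tr.sign_a2c[d] == -tr.sign_c2a[d])
        assert np.all(tr.sign_a2c[d] != 0)
        assert np.all(tr.sign_a2c[b] == -tr.sign_c2a[b])
        assert np.all(tr.sign_a2c[n] == 0) and np.all(tr.sign_c2a[n] == 0)

    def test_directional_paths_follow_their_signs(self, sim_default):
        tr = sim_default.truth
        d = tr.classes == "directional"
        for traj, signs in (("A2C", tr.sign_a2c), ("C2A", tr.sign_c2a)):
            p = tr.paths[traj][d]  # loci x reps x gens
            drift = (p[:, :, -1] - p[:, :, 0]).mean(axis=1)
            agree = np.sign(drift) == signs[d]
            assert agree.mean() >= 0.95

    def test_founder_heterozygosity_contrast(self, sim_default):
        # hidden reservoir: balanced loci nearly invariant in A founders,
        # intermediate in C founders
        tr = sim_default.truth
        b = tr.classes == "balanced"
        fa = tr.founder_freqs["FOUNDER_A"][b]
        fc = tr.founder_freqs["FOUNDER_C"][b]
        ha = (2 * fa * (1 - fa)).mean()
        hc = (2 * fc * (1 - fc)).mean()
        assert ha < 0.1 < hc

    def test_balanced_loci_never_fix_at_safe_equilibrium(self):
        # overdominance whose equilibrium sits several stationary-sd
        # above 0 never fixes either allele over the experiment horizon
        cfg = SimConfig(
            n_loci=60, n_selected=0, n_balanced=60, pop_size=500,
            n_replicates=5, hidden_freq_range=(0.15, 0.25), seed=11,
        )
        res = simulate_experiment(cfg)
        for t in ("A2C", "C2A"):
            p = res.truth.paths[t][res.truth.classes == "balanced"]
            assert np.all(p > 0) and np.all(p < 1)

    def test_deep_sample_tracks_same_pool(self, sim_default):
        std = sim_default.table
        j = std.sample_index("FA1")
        f_std = std.minor[:, j] / std.coverage[:, j]
        f_deep = sim_default.deep.minor[:, 0] / sim_default.deep.coverage[:, 0]
        assert np.corrcoef(f_std, f_deep)[0, 1] > 0.95
        assert sim_default.deep.coverage[:, 0].mean() > 700

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_loci=10, n_selected=8, n_balanced=8)
        with pytest.raises(ValueError):
            SimConfig(s=1.5)
        with pytest.raises(ValueError):
            SimConfig(pool_size=5000)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = SimConfig(n_loci=123, n_selected=10, n_balanced=10, seed=9)
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SimConfig.from_yaml(tmp_path / "c.yaml")
        assert back.n_loci == 123 and back.seed == 9
        assert back.sampled_generations["C2A"] == [33.0, 143.0, 182.0]


class TestGlmmSampler:
    def test_counts_within_bounds_and_reproducible(self):
        d = glmm_design(n_replicates=3)
        y1, n1 = simulate_bb_counts(
            d, [0.0, 0, 0, 0], 0.05, 0.1, 50, rng=np.random.default_rng(5)
        )
        y2, n2 = simulate_bb_counts(
            d, [0.0, 0, 0, 0], 0.05, 0.1, 50, rng=np.random.default_rng(5)
        )
        assert np.all(y1 <= n1) and np.all(y1 >= 0)
        np.testing.assert_array_equal(y1, y2)

    def test_mean_frequency_follows_linear_predictor(self):
        d = glmm_design(n_replicates=10)
        rng = np.random.default_rng(6)
        y, n = simulate_bb_counts(d, [-1.0, 0, 0, 0], 0.02, 0.0, 2000, rng=rng)
        f = (y.sum() / n.sum())
        assert f == pytest.approx(1 / (1 + np.e), abs=0.01)
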