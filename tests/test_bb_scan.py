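"""Beta-binomial GLMM likelihood, fitting, and genome scan."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import betabinom, binom

from evoltraj import bb_loglik, bb_logpmf, fit_bb_glmm, scan_genome
from evoltraj.bb_scan import trajectory_design
from evoltraj.simulate import glmm_design, simulate_bb_counts

from conftest import make_table


def _rho_to_ab(p, rho):
    return p * (1 - rho) / rho, (1 - p) * (1 - rho) / rho


class TestBbLogpmf:
    def test_binomial_limit(self):
        rng = np.random.default_rng(0)
        n = rng.integers(1, 200, 300)
        y = rng.integers(0, n + 1)
        p = rng.uniform(0.01, 0.99, 300)
        ours = bb_logpmf(y, n, p, 1e-10)
        ref = binom.logpmf(y, n, p)
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_matches_independent_beta_binomial_pmf(self):
        rng = np.random.default_rng(1)
        n = rng.integers(1, 200, 300)
        y = rng.integers(0, n + 1)
        p = rng.uniform(0.01, 0.99, 300)
        rho = rng.uniform(0.01, 0.5, 300)
        ours = np.array(
            [bb_logpmf(yi, ni, pi, ri) for yi, ni, pi, ri in zip(y, n, p, rho)]
        )
        a, b = _rho_to_ab(p, rho)
        ref = betabinom.logpmf(y, n, a, b)
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_bernoulli_and_binomial_closed_forms(self):
        assert bb_logpmf(1, 1, 0.5, 0.0) == pytest.approx(np.log(0.5))
        assert bb_logpmf(0, 1, 0.5, 0.0) == pytest.approx(np.log(0.5))
        from math import comb, log

        expected = log(comb(10, 3) * 0.3**3 * 0.7**7)
        assert bb_logpmf(3, 10, 0.3, 0.0) == pytest.approx(expected)


class TestBbLoglik:
    def _design(self):
        return pd.DataFrame(
            {"T": [0, 0, 1, 1], "G": [0.0, 10.0, 0.0, 10.0],
             "rep": ["a", "a", "b", "b"]}
        )

    def test_sums_pmf_over_observations(self):
        d = self._design()
        beta = np.array([-0.5, 0.2, 0.01, -0.02])
        u = np.array([0.1, -0.1])
        y = np.array([3, 5, 2, 8])
        n = np.array([20, 25, 18, 30])
        from scipy.special import expit

        X = np.column_stack([np.ones(4), d["T"], d["G"], d["T"] * d["G"]])
        eta = X @ beta + u[[0, 0, 1, 1]]
        p = expit(eta)
        a, b = _rho_to_ab(p, 0.1)
        expected = betabinom.logpmf(y, n, a, b).sum()
        assert bb_loglik(beta, 0.1, u, (y, n), d) == pytest.approx(expected)

    def test_input_validation(self):
        d = self._design()
        with pytest.raises(ValueError, match="phi"):
            bb_loglik([0, 0, 0, 0], -0.1, [0, 0], ([1] * 4, [10] * 4), d)
        with pytest.raises(ValueError, match="counts"):
            bb_loglik([0, 0, 0, 0], 0.1, [0, 0], ([11] * 4, [10] * 4), d)
        with pytest.raises(ValueError, match="observation"):
            bb_loglik([np.inf, 0, 0, 0], 0.1, [0, 0], ([1] * 4, [10] * 4), d)


class TestFitBbGlmm:
    def test_degenerate_locus_flagged_not_raised(self):
        d = glmm_design(n_replicates=2)
        y = np.zeros(len(d), dtype=int)
        n = np.full(len(d), 90)
        fit = fit_bb_glmm(y, n, d)
        assert not fit.converged and fit.reason == "no variation"
        fit2 = fit_bb_glmm(n, n, d)
        assert not fit2.converged and fit2.reason == "no variation"

    def test_matches_binomial_glm_without_overdispersion(self):
        # phi=0, sigma_u=0 data: ML estimates agree with an ordinary
        # binomial GLM within 1e-3 relative
        d = glmm_design(n_replicates=10)
        rng = np.random.default_rng(2)
        beta = np.array([-0.8, 0.3, 0.004, -0.006])
        y, n = simulate_bb_counts(d, beta, 0.0, 0.0, 5, 500.0, rng)
        X = np.column_stack([np.ones(len(d)), d["T"], d["G"], d["T"] * d["G"]])
        for i in range(5):
            glm = sm.GLM(
                np.column_stack([y[i], n[i] - y[i]]), X,
                family=sm.families.Binomial(),
            ).fit()
            ours = fit_bb_glmm(y[i], n[i], d)
            assert ours.converged
            np.testing.assert_allclose(ours.beta, glm.params, rtol=1e-3, atol=1e-4)

    def test_interaction_sign_recovery(self):
        d = glmm_design(n_replicates=10)
        rng = np.random.default_rng(3)
        nl = 40
        signs = np.where(np.arange(nl) % 2 == 0, 1.0, -1.0)
        beta = np.column_stack(
            [np.full(nl, -1.0), np.zeros(nl), np.zeros(nl), 0.03 * signs]
        )
        y, n = simulate_bb_counts(d, beta, 0.05, 0.1, nl, 90.0, rng)
        fitted = np.array([fit_bb_glmm(y[i], n[i], d).beta[3] for i in range(nl)])
        assert np.mean(np.sign(fitted) == signs) >= 0.95

    def test_laplace_and_quadrature_agree(self):
        d = glmm_design(n_replicates=10)
        rng = np.random.default_rng(4)
        y, n = simulate_bb_counts(
            d, [-1.0, 0.2, 0.005, 0.01], 0.05, 0.2, 3, 90.0, rng
        )
        for i in range(3):
            lap = fit_bb_glmm(y[i], n[i], d, method="laplace")
            agh = fit_bb_glmm(y[i], n[i], d, method="aghq")
            np.testing.assert_allclose(lap.beta, agh.beta, atol=1e-2)


class TestScanGenome:
    def test_single_locus_bonferroni_is_identity(self):
        d = glmm_design(n_replicates=5)
        rng = np.random.default_rng(5)
        y, n = simulate_bb_counts(d, [-1.0, 0, 0, 0], 0.05, 0.1, 1, 90.0, rng)
        groups = ["A2C" if t == 0 else "C2A" for t in d["T"]]
        reps = [int(r.split("_")[-1]) for r in d["rep"]]
        table = make_table(y, n, groups=groups, generations=d["G"], replicates=reps)
        res = scan_genome(table)
        assert res.n_tested == 1
        assert res.frame["padj_interaction"].iloc[0] == pytest.approx(
            min(1.0, res.frame["p_interaction"].iloc[0]), rel=1e-12
        )

    def test_strong_antiparallel_loci_recovered_exactly(self):
        # 10 strongly antiparallel loci among 90 null: the interaction
        # class contains exactly the signal loci at Bonferroni alpha=0.05
        d = glmm_design(n_replicates=10)
        rng = np.random.default_rng(6)
        nl = 100
        beta = np.column_stack(
            [np.full(nl, -0.5), np.zeros(nl), np.zeros(nl), np.zeros(nl)]
        )
        signal = np.arange(10)
        beta[signal, 3] = 0.025
        y, n = simulate_bb_counts(d, beta, 0.02, 0.05, nl, 90.0, rng)
        groups = ["A2C" if t == 0 else "C2A" for t in d["T"]]
        reps = [int(r.split("_")[-1]) for r in d["rep"]]
        table = make_table(y, n, groups=groups, generations=d["G"], replicates=reps)
        res = scan_genome(table)
        flagged = set(res.significant_loci("interaction"))
        assert flagged == set(signal)
        counts = res.class_counts()
        assert counts.get(("interaction",), 0) >= 8  # most are interaction-only

    def test_trajectory_design_built_from_metadata(self, sim_default):
        d = trajectory_design(sim_default.table)
        assert set(d["T"]) == {0, 1}
        assert len(d) == 60  # 2 trajectories x 10 reps x 3 generations
        assert d["rep"].nunique() == 20
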