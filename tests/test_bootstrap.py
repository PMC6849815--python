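"""Multiplier-bootstrap schemes: exact identities, oracles, distributional checks."""
import numpy as np
import pytest

import coxband as cb
from coxband.bootstrap import _workspace

from conftest import make_sample, random_sample


class TestMultipliers:
    @pytest.mark.parametrize("law,skew", [("normal", 0.0), ("poisson", 1.0),
                                          ("exponential", 2.0)])
    def test_moments(self, law, skew):
        g = cb.draw_multipliers(cb.MultiplierSpec(law, 2024), size=10 ** 6)
        assert abs(g.mean()) < 4e-3
        assert abs(g.var() - 1.0) < 0.01
        m3 = np.mean((g - g.mean()) ** 3)
        assert abs(m3 - skew) < 0.03 * max(1.0, abs(skew))

    def test_seed_reproducibility(self):
        a = cb.draw_multipliers(cb.MultiplierSpec("poisson", 7, n=50))
        b = cb.draw_multipliers(cb.MultiplierSpec("poisson", 7, n=50))
        np.testing.assert_array_equal(a, b)

    def test_unknown_law_rejected(self):
        with pytest.raises(ValueError, match="unknown multiplier law"):
            cb.MultiplierSpec("cauchy", 1)


class TestBootstrapScore:
    def test_zero_multipliers_zero_score(self, design_data):
        data, fit = design_data
        G = np.zeros(data.n_subjects)
        for inc in ("dN", "dM"):
            np.testing.assert_array_equal(
                cb.bootstrap_score(data, fit, G, inc), 0.0)

    def test_unit_multipliers_recover_score_equation(self, design_data):
        # G = 1 with dN increments gives U_tau(beta_hat) = 0
        data, fit = design_data
        u = cb.bootstrap_score(data, fit, np.ones(data.n_subjects), "dN")
        np.testing.assert_allclose(u, 0.0, atol=1e-9)

    def test_matches_loop_oracle(self):
        # hand n=4 dataset, random G: independent per-event loop summation
        rng = np.random.default_rng(8)
        s = random_sample(rng, n=4)
        fit = cb.fit_beta(s)
        G = rng.normal(0, 1, 4)
        expect = np.zeros(1)
        for i in range(4):
            if s.status[i] == 1:
                rs = cb.risk_set_sums(s, fit.beta, s.exit[i])
                expect += G[i] * (s.covariates[i] - rs.E)
        np.testing.assert_allclose(cb.bootstrap_score(s, fit, G, "dN"),
                                   expect, rtol=1e-10)

    def test_dm_mode_matches_martingale_sum(self, design_data):
        # dM-mode score = sum_i G_i sum_u (X_i - E_u) dMhat_i(u), by loops
        data, fit = design_data
        rng = np.random.default_rng(3)
        G = rng.normal(0, 1, data.n_subjects)
        mi = cb.martingale_increments(data, fit)
        E = fit._E[:, 0]
        X = data.covariates[:, 0]      # one row per subject here
        expect = sum(G[i] * np.sum((X[i] - E) * mi.dM[:, i])
                     for i in range(data.n_subjects))
        got = cb.bootstrap_score(data, fit, G, "dM")[0]
        assert got == pytest.approx(expect, rel=1e-9)


class TestBootstrapInformation:
    def test_zero_and_unit_multipliers(self, design_data):
        data, fit = design_data
        n = data.n_subjects
        np.testing.assert_array_equal(
            cb.bootstrap_information(data, fit, np.zeros(n)), 0.0)
        I1 = cb.bootstrap_information(data, fit, np.ones(n), "dN")
        # optional-variation matrix: sum over events of (X - E)^2, PSD
        ws = _workspace(fit, "dN")
        expect = np.einsum("ep,eq->pq", ws.event_X - fit._E[ws.k_of_event],
                           ws.event_X - fit._E[ws.k_of_event])
        np.testing.assert_allclose(I1, expect, rtol=1e-12)
        assert np.linalg.eigvalsh(I1).min() >= 0

    def test_mean_over_draws_is_optional_variation(self, design_data):
        # E[I* | data] = sum (X-E)^2 since E G^2 = 1
        data, fit = design_data
        rng = np.random.default_rng(17)
        n = data.n_subjects
        draws = np.mean([cb.bootstrap_information(data, fit,
                                                  rng.normal(0, 1, n))
                         for _ in range(3000)], axis=0)
        expect = cb.bootstrap_information(data, fit, np.ones(n))
        np.testing.assert_allclose(draws, expect, rtol=0.05)


class TestNullMultiplierIdentity:
    def test_both_schemes_reproduce_estimate_exactly(self, design_data):
        data, fit = design_data
        G = np.zeros(data.n_subjects)
        for fn in (cb.direct_replicate, cb.score_replicate):
            rep = fn(data, fit, G, "dN")
            np.testing.assert_array_equal(rep.beta_star, fit.beta)
            np.testing.assert_array_equal(rep.breslow_star.values,
                                          fit.breslow.values)


class TestSchemeAgreement:
    def test_score_at_beta_hat_coincides(self, design_data):
        # the reweighted-score-equation score at beta_hat equals the direct
        # perturbation bitwise for shared G (dN mode)
        data, fit = design_data
        G = np.random.default_rng(5).standard_normal((data.n_subjects, 1))
        ws = _workspace(fit, "dN")
        u_direct = ws.score_star(G)
        nu = ws.nu(G)
        u_ee = (ws.sum_Xe[:, None] + ws.TX.T @ G
                - np.einsum("kb,kp->pb", nu, ws.E))
        # algebraically identical; equality up to summation-order rounding
        np.testing.assert_allclose(u_direct, u_ee, rtol=0, atol=1e-10)


class TestScoreReplicate:
    def test_grid_search_oracle_positive_weights(self):
        # with all G_i + 1 > 0 the replicate maximizes the weighted log-PL
        rng = np.random.default_rng(21)
        s = random_sample(rng, n=30)
        fit = cb.fit_beta(s)
        G = rng.poisson(1.0, 30).astype(float) - 1.0
        G[G < 0] = 0.0                      # condition on positive weights
        rep = cb.score_replicate(s, fit, G)
        assert rep.converged
        w = G + 1.0
        grid = np.linspace(fit.beta[0] - 1.5, fit.beta[0] + 1.5, 30001)
        ev = np.flatnonzero(s.status == 1)
        at_risk = (s.exit[None, :] >= s.exit[ev][:, None])
        lp = np.zeros_like(grid)
        for j, b in enumerate(grid):
            wexp = np.exp(s.covariates[:, 0] * b)
            lp[j] = np.sum(w[ev] * (s.covariates[ev, 0] * b
                                    - np.log(at_risk @ wexp)))
        assert abs(rep.beta_star[0] - grid[np.argmax(lp)]) < 1e-4

    def test_direct_replicate_hand_arithmetic(self):
        # n=3, p=1 dataset, fixed G: check the closed-form baseline update
        s = make_sample([1.0, 2.0, 3.0], [1, 1, 0], [[0.0], [1.0], [-1.0]])
        fit = cb.fit_beta(s)
        G = np.array([0.4, -0.2, 0.1])
        rep = cb.direct_replicate(s, fit, G, "dN")
        b, bs = fit.beta[0], rep.beta_star[0]
        w = np.exp(s.covariates[:, 0] * b)
        S0_1, S0_2 = w.sum(), w[1] + w[2]
        E1 = (w * s.covariates[:, 0]).sum() / S0_1
        E2 = (w[1] * 1.0 + w[2] * -1.0) / S0_2
        lam1 = 1 / S0_1
        lam2 = lam1 + 1 / S0_2
        expect1 = lam1 - (bs - b) * E1 * (1 / S0_1) + G[0] / S0_1
        expect2 = (lam2 - (bs - b) * (E1 / S0_1 + E2 / S0_2)
                   + G[0] / S0_1 + G[1] / S0_2)
        np.testing.assert_allclose(rep.breslow_star.values[:2],
                                   [expect1, expect2], rtol=1e-12)


class TestEnsemble:
    def test_deterministic_under_seed(self, design_data):
        data, fit = design_data
        kw = dict(approach="score", increments="dN")
        e1 = cb.run_ensemble(data, fit, 50, cb.MultiplierSpec("poisson", 3), **kw)
        e2 = cb.run_ensemble(data, fit, 50, cb.MultiplierSpec("poisson", 3), **kw)
        np.testing.assert_array_equal(e1.lambda_star, e2.lambda_star)
        np.testing.assert_array_equal(e1.beta_star, e2.beta_star)

    def test_batch_matches_single_replicates(self, design_data):
        # the vectorized ensemble equals replicate-at-a-time computation
        data, fit = design_data
        for approach, fn in (("direct", cb.direct_replicate),
                             ("score", cb.score_replicate)):
            for inc in ("dN", "dM"):
                ens = cb.run_ensemble(data, fit, 8,
                                      cb.MultiplierSpec("exponential", 13),
                                      approach=approach, increments=inc)
                for b in range(8):
                    rep = fn(data, fit, ens.G[:, b], inc)
                    np.testing.assert_allclose(rep.beta_star, ens.beta_star[b],
                                               rtol=1e-9, atol=1e-12)
                    np.testing.assert_allclose(rep.breslow_star.values,
                                               ens.lambda_star[:, b],
                                               rtol=1e-9, atol=1e-12)

    def test_variance_star_matches_plugin(self, design_data):
        # ensemble variance of sqrt(n)(L*-L) tracks the plug-in sigma^2
        data, fit = design_data
        ens = cb.run_ensemble(data, fit, 2000, cb.MultiplierSpec("normal", 7),
                              approach="score", increments="dN")
        for t in (1.0, 2.0):
            assert ens.variance_at(t)[0] == pytest.approx(fit.variance(t),
                                                          rel=0.15)

    @pytest.mark.parametrize("law", ["normal", "poisson", "exponential"])
    def test_conditional_centering(self, design_data, law):
        # mean of beta* across replicates approaches beta_hat
        data, fit = design_data
        ens = cb.run_ensemble(data, fit, 1500, cb.MultiplierSpec(law, 31),
                              approach="score", increments="dN")
        bs = ens.beta_star[ens.converged, 0]
        se_mean = bs.std(ddof=1) / np.sqrt(bs.size)
        assert abs(bs.mean() - fit.beta[0]) < 6 * se_mean

    def test_low_dropout(self, design_data):
        data, fit = design_data
        for law in ("normal", "poisson", "exponential"):
            ens = cb.run_ensemble(data, fit, 500, cb.MultiplierSpec(law, 41),
                                  approach="score", increments="dN")
            assert ens.dropped / ens.B < 0.05


class TestDistributionalValidity:
    @pytest.mark.parametrize("approach", ["direct", "score"])
    def test_bootstrap_law_matches_sampling_law(self, approach):
        # Kolmogorov distance between sqrt(n)(beta_hat - beta_0) across
        # simulated datasets and sqrt(n)(beta* - beta_hat) across replicates
        sc = cb.SimulationScenario(n=400)
        stats = []
        for r in range(1000):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=616, spawn_key=(r,)))
            d = cb.generate_dataset(sc, rng)
            stats.append(np.sqrt(400) * (cb.fit_beta(d).beta[0] - 0.3))
        data = cb.generate_dataset(
            sc, np.random.default_rng(np.random.SeedSequence(entropy=616,
                                                             spawn_key=(0,))))
        fit = cb.fit_beta(data)
        ens = cb.run_ensemble(data, fit, 1000, cb.MultiplierSpec("normal", 5),
                              approach=approach)
        boot = np.sqrt(400) * (ens.beta_star[ens.converged, 0] - fit.beta[0])
        from scipy.stats import ks_2samp
        ks = ks_2samp(np.asarray(stats), boot).statistic
        assert ks < 0.08
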