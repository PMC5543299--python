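"""BYM model: CAR conditionals, conjugate updates, sampler behaviour, R-hat."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

import spatepi as sp
from spatepi.bym import tau_u_conditional_params, tau_v_conditional_params


@pytest.fixture(scope="module")
def grid_3x3():
    spec = sp.SimulationSpec(n_rows=3, n_cols=3, implants=())
    areas, edges = sp.simulate_lattice(spec)
    W = sp.build_weights(edges.itertuples(index=False, name=None), list(areas["id"]))
    return areas, W


class TestPriors:
    def test_prior_means_of_default_hyperparameters(self):
        p = sp.BYMPriors()
        assert p.prior_mean_tau_v == pytest.approx(100.0)  # 0.5 / 0.005
        assert p.prior_mean_tau_u == pytest.approx(1.0)    # 0.5 / 0.5

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            sp.BYMPriors(a_v=0.0)


class TestCarConditional:
    def test_mean_is_neighbor_average(self, path4_weights=None):
        W = sp.build_weights([(0, 1), (0, 2)], [0, 1, 2])
        v = np.array([0.0, 0.2, 0.4])
        mean, var = sp.car_conditional(v, W, tau_v=1.0, i=0)
        assert mean == pytest.approx(0.3)

    def test_single_neighbor(self):
        W = sp.build_weights([(0, 1)], [0, 1])
        mean, _ = sp.car_conditional(np.array([0.0, 0.7]), W, tau_v=1.0, i=0)
        assert mean == pytest.approx(0.7)

    def test_variance_precision_parameterization(self):
        W = sp.build_weights([(0, 1), (0, 2)], [0, 1, 2])
        _, var = sp.car_conditional(np.zeros(3), W, tau_v=2.0, i=0)
        assert var == pytest.approx(0.25)  # 1 / (tau * m_i)

    def test_island_rejected(self):
        W = sp.build_weights([(0, 1)], [0, 1, 2])
        with pytest.raises(ValueError, match="island"):
            sp.car_conditional(np.zeros(3), W, tau_v=1.0, i=2)


class TestConjugateUpdates:
    def test_tau_u_conditional_matches_brute_force_density(self):
        """Gamma(shape, rate) params reproduce prior x likelihood off-constant."""
        rng = np.random.default_rng(3)
        priors = sp.BYMPriors()
        for _ in range(5):
            u = rng.normal(0, 0.7, size=8)
            sh, rt = tau_u_conditional_params(u, priors)

            def logpost(tau):
                lp = stats.gamma.logpdf(tau, a=priors.a_u, scale=1 / priors.b_u)
                lp += np.sum(stats.norm.logpdf(u, 0, 1 / np.sqrt(tau)))
                return lp

            for t1, t2 in [(0.5, 2.0), (1.0, 3.7)]:
                direct = logpost(t2) - logpost(t1)
                conj = stats.gamma.logpdf(t2, a=sh, scale=1 / rt) - stats.gamma.logpdf(
                    t1, a=sh, scale=1 / rt
                )
                assert direct == pytest.approx(conj, abs=1e-10)

    def test_tau_v_conditional_matches_icar_density(self, grid_3x3):
        """ICAR kernel: pairwise differences and rank deficiency I - k."""
        _, W = grid_3x3
        rng = np.random.default_rng(4)
        priors = sp.BYMPriors()
        v = rng.normal(0, 0.5, size=9)
        v -= v.mean()
        sh, rt = tau_v_conditional_params(v, W, priors)
        pairs = W.edge_pairs()
        ss = float(((v[pairs[:, 0]] - v[pairs[:, 1]]) ** 2).sum())

        def logpost(tau):
            lp = stats.gamma.logpdf(tau, a=priors.a_v, scale=1 / priors.b_v)
            lp += (W.n - 1) / 2 * np.log(tau) - tau * ss / 2  # one component
            return lp

        for t1, t2 in [(5.0, 20.0), (1.0, 80.0)]:
            direct = logpost(t2) - logpost(t1)
            conj = stats.gamma.logpdf(t2, a=sh, scale=1 / rt) - stats.gamma.logpdf(
                t1, a=sh, scale=1 / rt
            )
            assert direct == pytest.approx(conj, abs=1e-10)


class TestGelmanRubin:
    def test_identical_chains_hand_value(self):
        assert sp.gelman_rubin([[1, 2, 3, 4], [1, 2, 3, 4]]) == pytest.approx(
            np.sqrt(0.75)
        )

    def test_approaches_one_for_long_iid_chains(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(2, 10_000))
        assert sp.gelman_rubin(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_exceed_one(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(size=(2, 500))
        chains[1] += 5.0
        assert sp.gelman_rubin(chains) > 2.0

    def test_degenerate_chains_rejected(self):
        with pytest.raises(ValueError):
            sp.gelman_rubin([[0, 0], [0, 0]])


class TestSampler:
    def test_identical_areas_give_symmetric_posterior(self, grid_3x3):
        areas, W = grid_3x3
        df = areas.copy()
        df["cases"] = 10
        df["expected"] = 8.0
        cfg = sp.MCMCConfig(n_iter=4000, n_burn=1000, n_chains=2, thin=2, seed=1)
        post = sp.fit_bym(df, W, config=cfg)
        summ = sp.summarize_posterior(post)
        # all areas are exchangeable: medians agree and center near O/E = 1.25
        assert summ["sir_bym"].max() - summ["sir_bym"].min() < 0.25
        assert summ["sir_bym"].mean() == pytest.approx(10 / 8, abs=0.2)
        assert (summ["sir_bym"] > 0).all()

    def test_sum_to_zero_constraint_on_v(self, grid_3x3):
        areas, W = grid_3x3
        df = areas.copy()
        rng = np.random.default_rng(0)
        df["expected"] = 5.0
        df["cases"] = rng.poisson(5.0, size=9)
        cfg = sp.MCMCConfig(n_iter=1500, n_burn=500, n_chains=2, thin=1, seed=3)
        post = sp.fit_bym(df, W, config=cfg)
        sums = post.v.sum(axis=2)
        assert np.max(np.abs(sums)) < 1e-10

    def test_single_area_nonspatial_matches_quadrature(self):
        """With a flat baseline the exact posterior of theta is Gamma(O, E)."""
        O_val, E_val = 7, 2.0
        df = pd.DataFrame({"id": [0], "x": [0.0], "y": [0.0], "pop": [1.0],
                           "cases": [O_val], "expected": [E_val]})
        W = sp.build_weights([], [0])
        cfg = sp.MCMCConfig(n_iter=30_000, n_burn=5_000, n_chains=2, thin=2, seed=5)
        post = sp.fit_bym(df, W, config=cfg, spatial=False)
        theta = post.theta.reshape(-1)

        # quadrature oracle on eta = log(theta): density ∝ exp(O*eta - E*e^eta)
        def dens(eta):
            return np.exp(O_val * eta - E_val * np.exp(eta))

        grid = np.linspace(-6, 6, 4001)
        norm = integrate.simpson(dens(grid), x=grid)
        mean_quad = integrate.simpson(np.exp(grid) * dens(grid), x=grid) / norm
        assert mean_quad == pytest.approx(O_val / E_val, rel=1e-4)
        assert theta.mean() == pytest.approx(mean_quad, rel=0.1)

    def test_islands_rejected_for_spatial_fit(self):
        df = pd.DataFrame({"id": [0, 1, 2], "x": [0.0, 1, 2], "y": 0.0,
                           "pop": 1.0, "cases": [1, 2, 3], "expected": [2.0, 2, 2]})
        W = sp.build_weights([(0, 1)], [0, 1, 2])
        with pytest.raises(ValueError, match="island"):
            sp.fit_bym(df, W, config=sp.MCMCConfig(n_iter=100, n_burn=10, seed=0))

    def test_nonpositive_expected_rejected(self, grid_3x3):
        areas, W = grid_3x3
        df = areas.copy()
        df["cases"] = 1
        df["expected"] = 0.0
        with pytest.raises(ValueError, match="expected"):
            sp.fit_bym(df, W)

    def test_summary_requires_draws(self):
        post = sp.BYMPosterior((0,), np.empty((2, 0)), np.empty((2, 0, 1)),
                               np.empty((2, 0, 1)), np.empty((2, 0)),
                               np.empty((2, 0)), {}, {})
        with pytest.raises(ValueError):
            sp.summarize_posterior(post)

    def test_median_of_constant_draws(self):
        draws = np.full((2, 101, 1), 2.5)
        post = sp.BYMPosterior((7,), np.zeros((2, 101)), np.log(draws),
                               np.zeros((2, 101, 1)), np.ones((2, 101)),
                               np.ones((2, 101)), {}, {})
        assert sp.summarize_posterior(post)["sir_bym"][0] == pytest.approx(2.5)
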