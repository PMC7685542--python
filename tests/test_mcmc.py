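import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import anaemap as am
from anaemap.mcmc import ALL_BLOCKS


def toy_panel():
    cases = np.array([[4.0, 9.0], [7.0, 2.0], [11.0, 6.0]])
    N = np.array([[50.0, 80.0], [70.0, 40.0], [90.0, 60.0]])
    panel = am.CountPanel(
        ("a0", "a1", "a2"),
        cases,
        N,
        ((2016, 1), (2016, 2)),
    )
    graph = am.graph_from_edge_list([(0, 1), (1, 2)], 3)
    return panel, graph


def random_state(I, T, seed=0):
    rng = np.random.default_rng(seed)
    return am.ModelState(
        alpha=0.15,
        u=rng.normal(0, 0.3, I),
        v=rng.normal(0, 0.3, I),
        xi=rng.normal(0, 0.3, T),
        nu=rng.normal(0, 0.3, (I, T)),
        rho=0.4,
        tau_u=2.0,
        tau_v=3.0,
        tau_xi=1.5,
        tau_nu=2.5,
        r=0.4,
    )


class TestInitializeState:
    def test_seed_determinism(self, small_panel):
        _, panel, _, graph = small_panel
        E = am.compute_expected(panel)
        s1 = am.initialize_state(panel, E, graph, 7)
        s2 = am.initialize_state(panel, E, graph, 7)
        np.testing.assert_array_equal(s1.u, s2.u)
        np.testing.assert_array_equal(s1.nu, s2.nu)

    def test_alpha_zero_under_internal_standardisation(self, small_panel):
        _, panel, _, graph = small_panel
        E = am.compute_expected(panel)
        assert am.initialize_state(panel, E, graph, 3).alpha == pytest.approx(
            0.0
        )

    def test_chains_with_different_seeds_differ_everywhere(self, small_panel):
        _, panel, _, graph = small_panel
        E = am.compute_expected(panel)
        s1 = am.initialize_state(panel, E, graph, 1)
        s2 = am.initialize_state(panel, E, graph, 2)
        for name in ("u", "v", "xi", "nu"):
            assert not np.allclose(getattr(s1, name), getattr(s2, name))


class TestLogPosterior:
    def test_component_sum_oracle(self):
        """log_posterior equals independently assembled components."""
        panel, graph = toy_panel()
        E = am.compute_expected(panel)
        state = random_state(3, 2)
        priors = am.PriorConfig()
        a, b = priors.gamma_shape, priors.gamma_rate

        lik = sum(
            am.nb_log_pmf(
                panel.cases[i, t],
                E.E[i, t] * am.relative_risk(state, i, t),
                state.r,
            )
            for i in range(3)
            for t in range(2)
        )
        icar = am.icar_log_density(state.u, state.tau_u, graph)
        vprior = stats.norm.logpdf(
            state.v, scale=1 / np.sqrt(state.tau_v)
        ).sum()
        ar1 = am.ar1_log_density(state.xi, state.rho, state.tau_xi)
        nuprior = stats.norm.logpdf(
            state.nu, scale=1 / np.sqrt(state.tau_nu)
        ).sum()
        taus = sum(
            stats.gamma.logpdf(tau, a, scale=1 / b)
            for tau in (state.tau_u, state.tau_v, state.tau_xi, state.tau_nu)
        )
        # 1/r ~ Gamma(a, b) expressed in r with its Jacobian
        rprior = stats.gamma.logpdf(1 / state.r, a, scale=1 / b) - 2 * np.log(
            state.r
        )
        oracle = lik + icar + vprior + ar1 + nuprior + taus + rprior
        assert am.log_posterior(panel, E, graph, priors, state) == pytest.approx(
            oracle, abs=1e-9
        )

    def test_invariant_to_constant_shift_between_u_and_alpha(self):
        panel, graph = toy_panel()
        E = am.compute_expected(panel)
        priors = am.PriorConfig()
        state = random_state(3, 2)
        lp0 = am.log_posterior(panel, E, graph, priors, state)
        shifted = state.copy()
        shifted.u += 0.8
        shifted.alpha -= 0.8
        assert am.log_posterior(panel, E, graph, priors, shifted) == pytest.approx(
            lp0, abs=1e-9
        )

    def test_prior_pulls_u_toward_neighbour_mean_without_data(self):
        panel, graph = toy_panel()
        blank = am.CountPanel(
            panel.area_ids,
            np.full((3, 2), np.nan),
            panel.denominators,
            panel.quarter_calendar,
        )
        E = am.ExpectedCounts(E=np.full((3, 2), 1.0))
        priors = am.PriorConfig()
        state = random_state(3, 2)
        state.u[:] = [0.0, 1.0, 0.0]
        closer = state.copy()
        closer.u[1] = 0.4
        assert am.log_posterior(blank, E, graph, priors, closer) > (
            am.log_posterior(blank, E, graph, priors, state)
        )


class TestRunMcmc:
    def test_bit_identical_reproducibility(self, small_panel):
        _, panel, _, graph = small_panel
        cfg = am.McmcConfig(n_chains=2, n_iter=250, n_burnin=50, seed=11)
        c1 = am.run_mcmc(panel, None, graph, config=cfg)
        c2 = am.run_mcmc(panel, None, graph, config=cfg)
        for name in c1.draws:
            np.testing.assert_array_equal(c1.draws[name], c2.draws[name])
        assert not np.array_equal(c1.draws["u"][0], c1.draws["u"][1])

    def test_adaptation_frozen_after_burnin(self, small_panel):
        """Proposal scales depend only on the burn-in segment."""
        _, panel, _, graph = small_panel
        short = am.run_mcmc(
            panel, None, graph,
            config=am.McmcConfig(n_chains=1, n_iter=400, n_burnin=200, seed=4),
        )
        long = am.run_mcmc(
            panel, None, graph,
            config=am.McmcConfig(n_chains=1, n_iter=900, n_burnin=200, seed=4),
        )
        assert short.proposal_scales[0] == long.proposal_scales[0]

    def test_degenerate_panel_concentrates_alpha_at_zero(self):
        """No signal beyond the offset: posterior risk stays near 1."""
        I, T = 9, 4
        N = np.full((I, T), 10_000.0)
        cases = 0.2 * N  # cases exactly equal expected counts
        panel = am.CountPanel(
            tuple(f"a{k}" for k in range(I)),
            cases,
            N,
            tuple((2016, q + 1) for q in range(T)),
        )
        graph = am.lattice_graph(I, (3, 3))
        chains = am.run_mcmc(
            panel, None, graph,
            config=am.McmcConfig(n_chains=2, n_iter=1500, n_burnin=500, seed=2),
        )
        assert abs(np.median(chains.stacked("alpha"))) < 0.05
        fitted = np.median(chains.risk_draws(), axis=0)
        assert np.abs(np.log(fitted)).max() < 0.2

    def test_r_only_sampling_matches_profile_likelihood(self):
        """With all random effects held at truth, the posterior of r peaks
        where the 1-D profile log-likelihood does."""
        cfg = am.GeneratorConfig(n_areas=20, n_times=6, seed=13)
        panel, truth, graph = am.generate_panel(cfg)
        E = am.true_expected(panel, cfg)

        grid = np.linspace(0.05, 1.2, 200)
        prof = [
            am.panel_log_likelihood(
                panel,
                E,
                am.ModelState(**{**truth.__dict__, "r": float(r)}),
            )
            for r in grid
        ]
        r_star = float(grid[int(np.argmax(prof))])

        start = truth.copy()
        chains = am.run_mcmc(
            panel, E, graph,
            config=am.McmcConfig(n_chains=2, n_iter=1500, n_burnin=300, seed=3),
            sample_blocks=("r",),
            initial_states=[start, start.copy()],
        )
        r_med = float(np.median(chains.stacked("r")))
        assert r_med == pytest.approx(r_star, abs=0.1)
        assert abs(r_star - cfg.r) < 0.15  # profile itself sits near truth

    def test_dimension_mismatch_rejected(self, small_panel):
        _, panel, _, _ = small_panel
        graph = am.lattice_graph(5)
        with pytest.raises(ValueError, match="areas"):
            am.NegBinCARModel(n_iter=10, n_burnin=1).fit(panel, graph)

    def test_unknown_block_rejected(self, small_panel):
        _, panel, _, graph = small_panel
        with pytest.raises(ValueError, match="unknown"):
            am.run_mcmc(
                panel, None, graph,
                config=am.McmcConfig(n_chains=1, n_iter=20, n_burnin=2),
                sample_blocks=("bogus",),
            )

    def test_chain_shapes_and_state_invariants(self, small_fit):
        panel, model = small_fit
        ch = model.chains_
        assert ch.get("alpha").shape == (2, 600)
        assert ch.get("nu").shape == (2, 600, panel.n_areas, panel.n_times)
        assert (ch.stacked("r") > 0).all()
        assert (np.abs(ch.stacked("rho")) < 1).all()
        for name in ("tau_u", "tau_v", "tau_xi", "tau_nu"):
            assert (ch.stacked(name) > 0).all()
        # u is recentred: sum-to-zero holds in every stored draw
        np.testing.assert_allclose(
            ch.stacked("u").sum(axis=1), 0.0, atol=1e-9
        )

    def test_estimator_sklearn_params_round_trip(self):
        model = am.NegBinCARModel(n_iter=100, n_burnin=10, seed=3)
        params = model.get_params()
        assert params["n_iter"] == 100
        clone = am.NegBinCARModel(**params)
        assert clone.get_params() == params

    def test_predict_returns_fitted_counts(self, small_fit):
        panel, model = small_fit
        fitted = model.predict()
        assert fitted.shape == (panel.n_areas, panel.n_times)
        obs = panel.observed_mask
        # posterior fitted counts track the data at this strong a signal
        corr = np.corrcoef(fitted[obs], panel.cases[obs])[0, 1]
        assert corr > 0.8
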