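import numpy as np
import pytest

import anaemap as am


@pytest.fixture(scope="session")
def small_panel():
    """12-area x 4-quarter synthetic panel with known truth."""
    cfg = am.GeneratorConfig(n_areas=12, n_times=4, seed=42)
    panel, truth, graph = am.generate_panel(cfg)
    return cfg, panel, truth, graph


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """A quick 2-chain fit reused by reporting/diagnostics structure tests."""
    cfg, panel, truth, graph = small_panel
    model = am.NegBinCARModel(
        n_chains=2, n_iter=900, n_burnin=300, seed=5
    ).fit(panel, graph)
    return panel, model


def identity_chains(panel, n_chains=2, n_draws=5):
    """PosteriorChains with every draw at pi == 1 (all effects zero)."""
    I, T = panel.n_areas, panel.n_times
    z = lambda *shape: np.zeros((n_chains, n_draws, *shape))
    draws = {
        "alpha": z(),
        "rho": z(),
        "r": np.full((n_chains, n_draws), 0.5),
        "tau_u": np.ones((n_chains, n_draws)),
        "tau_v": np.ones((n_chains, n_draws)),
        "tau_xi": np.ones((n_chains, n_draws)),
        "tau_nu": np.ones((n_chains, n_draws)),
        "u": z(I),
        "v": z(I),
        "xi": z(T),
        "nu": z(I, T),
    }
    cfg = am.McmcConfig(n_chains=n_chains, n_iter=n_draws + 1, n_burnin=0)
    return am.PosteriorChains(
        draws=draws,
        config=cfg,
        seed=0,
        acceptance=[],
        area_ids=panel.area_ids,
        quarter_calendar=panel.quarter_calendar,
    )
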