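"""Metropolis-within-Gibbs sampler for the NB spatio-temporal CAR model.

Update kernel, one sweep:

* ``u``  — single-site updates, vectorised over graph-colour classes;
  the proposal is the ICAR full-conditional Gaussian, so the Metropolis
  correction reduces to the NB likelihood ratio.
* ``v``, ``nu`` — elementwise Metropolis (cells are conditionally
  independent).  Sweeps alternate between an adaptive random walk and an
  independence proposal from the conditional prior N(0, 1/tau); the mixture
  keeps the precision/effect "funnel" mixing when the likelihood is weak.
* ``xi`` — single-site updates over time-parity classes with the stationary
  AR(1) full-conditional proposal and a likelihood correction.
* ``alpha`` — scalar random walk (flat prior).
* ``rho`` — random walk on logit((rho+1)/2), uniform prior on (-1, 1).
* precisions — conjugate Gibbs from the Gamma priors and quadratic forms.
* ``r`` — random walk on log r with a Gamma prior on 1/r.
* interleaved likelihood-invariant Gibbs moves along the model's soft
  non-identifiabilities: the BYM split (re-drawing ``u`` given the sum
  ``u + v``) and the centering directions that trade the means of ``v``,
  ``xi`` and ``nu`` against the flat-prior intercept.  Both are exact
  conditional draws, so they carry no Metropolis correction; without them
  the confounded blocks mix by random walk only.
* sum-to-zero recentring of ``u`` per connected component, compensated
  through ``alpha`` (exact on a connected graph).

Proposal scales adapt only during burn-in; the post-burn-in kernel is
fixed.  Runs are bit-reproducible for a fixed (seed, config, inputs).

The scikit-learn-style estimator :class:`NegBinCARModel` is the primary
interface; :func:`run_mcmc` is a thin functional wrapper over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, gammaln
from sklearn.base import BaseEstimator

from .graphs import AdjacencyGraph, icar_pairwise_sum
from .model import (
    CountPanel,
    ExpectedCounts,
    ModelState,
    PriorConfig,
    ar1_log_density,
    compute_expected,
    iid_normal_log_density,
    panel_log_likelihood,
)

SCALAR_PARAMS = ("alpha", "rho", "r", "tau_u", "tau_v", "tau_xi", "tau_nu")
ALL_BLOCKS = ("u", "v", "xi", "nu", "alpha", "rho", "precisions", "r")


class InitializationError(RuntimeError):
    pass


@dataclass(frozen=True)
class McmcConfig:
    """Chain-length and tuning configuration.

    The defaults mirror the full analysis protocol (two chains of 71,000
    iterations, 4,000 burn-in); :meth:`desk_scale` gives the documented
    reduced preset used for routine testing and synthetic studies.
    """

    n_chains: int = 2
    n_iter: int = 71000
    n_burnin: int = 4000
    thin: int = 1
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.n_burnin < self.n_iter:
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")

    @classmethod
    def desk_scale(cls, **overrides) -> "McmcConfig":
        base = dict(n_chains=2, n_iter=6000, n_burnin=1000)
        base.update(overrides)
        return cls(**base)


@dataclass
class PosteriorChains:
    """Post-burn-in, thinned draws from all chains.

    ``draws[name]`` has shape (n_chains, n_kept, *param_shape).
    """

    draws: dict[str, np.ndarray]
    config: McmcConfig
    seed: int
    acceptance: list[dict[str, float]]
    area_ids: tuple[str, ...]
    quarter_calendar: tuple[tuple[int, int], ...]
    proposal_scales: list = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.draws["alpha"].shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws["alpha"].shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.draws[name]

    def stacked(self, name: str) -> np.ndarray:
        arr = self.draws[name]
        return arr.reshape(arr.shape[0] * arr.shape[1], *arr.shape[2:])

    def risk_draws(self) -> np.ndarray:
        """Relative-risk draws pi_it, shape (n_draws_total, I, T)."""
        alpha = self.stacked("alpha")
        u = self.stacked("u")
        v = self.stacked("v")
        xi = self.stacked("xi")
        nu = self.stacked("nu")
        return np.exp(
            alpha[:, None, None]
            + u[:, :, None]
            + v[:, :, None]
            + xi[:, None, :]
            + nu
        )

    def summary(self):
        """Median, 95% interval, split R-hat and ESS for scalar parameters."""
        import pandas as pd

        from .diagnostics import effective_sample_size, gelman_rubin

        rows = []
        for name in SCALAR_PARAMS:
            arr = self.draws[name]
            flat = arr.ravel()
            rhat = (
                gelman_rubin(arr) if self.n_chains >= 2 else np.nan
            )
            ess = float(
                sum(effective_sample_size(arr[c]) for c in range(arr.shape[0]))
            )
            rows.append(
                {
                    "parameter": name,
                    "median": float(np.median(flat)),
                    "q2.5": float(np.quantile(flat, 0.025)),
                    "q97.5": float(np.quantile(flat, 0.975)),
                    "rhat": rhat,
                    "ess": ess,
                }
            )
        return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# likelihood workspace
# ---------------------------------------------------------------------------


class _Workspace:
    """Precomputed panel quantities used inside the sweep."""

    def __init__(self, panel: CountPanel, E: ExpectedCounts):
        self.mask = panel.observed_mask
        self.w = self.mask.astype(float)
        self.y = np.where(self.mask, np.nan_to_num(panel.cases), 0.0)
        # offset: fill unobserved cells with 1 so exp/log stay finite; the
        # 0 weight removes them from every sum
        self.Efill = np.where(
            self.mask & np.isfinite(E.E) & (E.E > 0), E.E, 1.0
        )
        if np.any(self.mask & ~(np.isfinite(E.E) & (E.E > 0))):
            raise ValueError("expected counts must be positive on observed cells")
        self.logE = np.log(self.Efill)
        self.has_obs = bool(self.mask.any())
        flat = np.flatnonzero(self.mask.ravel())
        self.obs_idx = flat
        self.y_obs = self.y.ravel()[flat]
        self.sum_gammaln_y1 = float(np.sum(gammaln(self.y_obs + 1.0)))

    def f_terms(self, mu: np.ndarray, y: np.ndarray, w: np.ndarray, r: float):
        """Per-cell weighted log-likelihood kernel in mu (r-terms cached out):
        w * [ y log mu - (1/r + y) log1p(r mu) ]."""
        if not self.has_obs:
            return np.zeros(np.broadcast_shapes(np.shape(mu), np.shape(w)))
        return w * (y * np.log(mu) - (1.0 / r + y) * np.log1p(r * mu))

    def loglik_rows(self, mu_rows, rows, r: float) -> np.ndarray:
        if not self.has_obs:
            return np.zeros(np.shape(mu_rows)[0])
        return self.f_terms(mu_rows, self.y[rows], self.w[rows], r).sum(axis=1)

    def loglik_cols(self, mu_cols, cols, r: float) -> np.ndarray:
        if not self.has_obs:
            return np.zeros(np.shape(mu_cols)[1])
        return self.f_terms(mu_cols, self.y[:, cols], self.w[:, cols], r).sum(
            axis=0
        )

    def loglik_total_kernel(self, mu, r: float) -> float:
        if not self.has_obs:
            return 0.0
        return float(self.f_terms(mu, self.y, self.w, r).sum())

    def loglik_total_full(self, mu, r: float) -> float:
        """Full NB log likelihood including the r-dependent gamma terms."""
        if not self.has_obs:
            return 0.0
        n = 1.0 / r
        mu_obs = mu.ravel()[self.obs_idx]
        gam = float(
            np.sum(gammaln(self.y_obs + n)) - len(self.y_obs) * gammaln(n)
        )
        ker = float(
            np.sum(
                self.y_obs * np.log(mu_obs)
                - (n + self.y_obs) * np.log1p(r * mu_obs)
            )
        )
        # y log r term folded in so this matches nb_log_pmf summed
        return gam + ker + float(np.sum(self.y_obs)) * np.log(r) - self.sum_gammaln_y1


# ---------------------------------------------------------------------------
# initialisation and joint density
# ---------------------------------------------------------------------------


def initialize_state(
    panel: CountPanel, E: ExpectedCounts, graph: AdjacencyGraph, seed: int
) -> ModelState:
    """Deterministic-by-seed starting state with small random-effect jitter."""
    rng = np.random.default_rng(seed)
    obs = panel.observed_mask
    if obs.any():
        alpha = float(np.log(panel.cases[obs].sum() / E.E[obs].sum()))
    else:
        alpha = 0.0
    I, T = panel.n_areas, panel.n_times
    u = rng.normal(0.0, 0.1, I)
    u[graph.islands] = 0.0
    for comp in range(graph.n_components):
        sel = (graph.component_labels == comp) & (graph.degrees > 0)
        if sel.any():
            u[sel] -= u[sel].mean()
    return ModelState(
        alpha=alpha,
        u=u,
        v=rng.normal(0.0, 0.1, I),
        xi=rng.normal(0.0, 0.1, T),
        nu=rng.normal(0.0, 0.1, (I, T)),
        rho=0.0,
        tau_u=1.0,
        tau_v=1.0,
        tau_xi=1.0,
        tau_nu=1.0,
        r=0.5,
    )


def _log_gamma_pdf(x: float, shape: float, rate: float) -> float:
    return float(
        shape * np.log(rate)
        - gammaln(shape)
        + (shape - 1.0) * np.log(x)
        - rate * x
    )


def _log_prior_r(r: float, priors: PriorConfig) -> float:
    """Prior on r induced by 1/r ~ Gamma(shape, rate)."""
    a, b = priors.gamma_shape, priors.gamma_rate
    return float(
        a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(r) - b / r
    )


def log_posterior(
    panel: CountPanel,
    E: ExpectedCounts,
    graph: AdjacencyGraph,
    priors: PriorConfig,
    state: ModelState,
) -> float:
    """Joint log density (up to a constant): likelihood plus all priors."""
    from .graphs import icar_log_density

    lp = panel_log_likelihood(panel, E, state)
    lp += icar_log_density(state.u, state.tau_u, graph)
    lp += iid_normal_log_density(state.v, state.tau_v)
    lp += ar1_log_density(state.xi, state.rho, state.tau_xi)
    lp += iid_normal_log_density(state.nu, state.tau_nu)
    for tau in (state.tau_u, state.tau_v, state.tau_xi, state.tau_nu):
        lp += _log_gamma_pdf(tau, priors.gamma_shape, priors.gamma_rate)
    lp += _log_prior_r(state.r, priors)
    # alpha flat, rho uniform on (-1,1): constants
    return float(lp)


# ---------------------------------------------------------------------------
# single chain
# ---------------------------------------------------------------------------


def _run_chain(
    panel: CountPanel,
    E: ExpectedCounts,
    graph: AdjacencyGraph,
    priors: PriorConfig,
    cfg: McmcConfig,
    chain_seed: int,
    sample_blocks: Optional[Sequence[str]],
    initial_state: Optional[ModelState],
):
    rng = np.random.default_rng(chain_seed)
    ws = _Workspace(panel, E)
    blocks = set(ALL_BLOCKS if sample_blocks is None else sample_blocks)
    unknown = blocks - set(ALL_BLOCKS)
    if unknown:
        raise ValueError(f"unknown sample blocks: {sorted(unknown)}")

    state = (
        initial_state.copy()
        if initial_state is not None
        else initialize_state(panel, E, graph, chain_seed)
    )
    lp0 = log_posterior(panel, E, graph, priors, state)
    if not np.isfinite(lp0):
        raise InitializationError(
            "non-finite log posterior at the initial state: "
            f"alpha={state.alpha:.4g}, r={state.r:.4g}, "
            f"tau=({state.tau_u:.4g},{state.tau_v:.4g},"
            f"{state.tau_xi:.4g},{state.tau_nu:.4g}), "
            f"max|u|={np.max(np.abs(state.u)):.4g}"
        )

    I, T = panel.n_areas, panel.n_times
    deg = graph.degrees
    A = graph.adjacency
    colors = graph.coloring
    color_classes = [
        np.flatnonzero((colors == c) & (deg > 0))
        for c in range(colors.max() + 1 if I else 0)
    ]
    color_classes = [s for s in color_classes if len(s)]
    comp_sets = [
        np.flatnonzero((graph.component_labels == c) & (deg > 0))
        for c in range(graph.n_components)
    ]
    comp_sets = [s for s in comp_sets if len(s)]
    connected = graph.n_components == 1 and len(graph.islands) == 0
    t_even = np.arange(0, T, 2)
    t_odd = np.arange(1, T, 2)
    a0, b0 = priors.gamma_shape, priors.gamma_rate

    # adaptive proposal scales (random-walk blocks only)
    log_step = {"v": np.log(0.3), "nu": np.log(0.5), "xi": np.log(0.2),
                "alpha": np.log(0.1), "rho": np.log(0.5), "r": np.log(0.3),
                "u_scale": np.log(0.1), "nu_scale": np.log(0.1),
                "uv_scale": np.log(0.3), "ridge": np.log(0.2)}
    # the r/nu dispersion ridge is the slowest direction: repeat the move,
    # and give one repetition a fixed wide step so the chain can hop between
    # the dispersion-allocation modes rather than only diffuse along it
    ridge_scales = (1.0, 1.0, 1.0, 5.0)
    window = {k: [0.0, 0.0] for k in log_step}  # accepted, proposed
    accepted = {k: 0.0 for k in ALL_BLOCKS}
    proposed = {k: 0.0 for k in ALL_BLOCKS}

    n_kept = (cfg.n_iter - cfg.n_burnin + cfg.thin - 1) // cfg.thin
    out = {
        "alpha": np.empty(n_kept),
        "rho": np.empty(n_kept),
        "r": np.empty(n_kept),
        "tau_u": np.empty(n_kept),
        "tau_v": np.empty(n_kept),
        "tau_xi": np.empty(n_kept),
        "tau_nu": np.empty(n_kept),
        "u": np.empty((n_kept, I)),
        "v": np.empty((n_kept, I)),
        "xi": np.empty((n_kept, T)),
        "nu": np.empty((n_kept, I, T)),
    }

    def current_mu():
        return ws.Efill * np.exp(
            state.alpha
            + state.u[:, None]
            + state.v[:, None]
            + state.xi[None, :]
            + state.nu
        )

    def ar1_quad(xi, rho):
        return (1.0 - rho**2) * xi[0] ** 2 + float(
            np.sum((xi[1:] - rho * xi[:-1]) ** 2)
        )

    kept = 0
    for sweep in range(cfg.n_iter):
        mu = current_mu()
        r = state.r
        rw_sweep = sweep % 2 == 0  # v/nu alternate RW and prior proposals

        # ---- structured spatial effect u --------------------------------
        if "u" in blocks:
            for S in color_classes:
                nb_sum = A[S] @ state.u
                cond_mean = nb_sum / deg[S]
                cond_sd = 1.0 / np.sqrt(state.tau_u * deg[S])
                prop = cond_mean + cond_sd * rng.standard_normal(len(S))
                ratio = np.exp(prop - state.u[S])
                mu_new = mu[S] * ratio[:, None]
                delta = ws.loglik_rows(mu_new, S, r) - ws.loglik_rows(
                    mu[S], S, r
                )
                acc = np.log(rng.random(len(S))) < delta
                state.u[S[acc]] = prop[acc]
                mu[S[acc]] = mu_new[acc]
                accepted["u"] += acc.sum()
                proposed["u"] += len(S)

        # ---- unstructured spatial effect v ------------------------------
        if "v" in blocks:
            if rw_sweep:
                step = np.exp(log_step["v"])
                prop = state.v + step * rng.standard_normal(I)
                prior_delta = -0.5 * state.tau_v * (prop**2 - state.v**2)
            else:
                prop = rng.standard_normal(I) / np.sqrt(state.tau_v)
                prior_delta = 0.0  # prior cancels proposal
            ratio = np.exp(prop - state.v)
            mu_new = mu * ratio[:, None]
            delta = (
                ws.loglik_rows(mu_new, slice(None), r)
                - ws.loglik_rows(mu, slice(None), r)
                + prior_delta
            )
            acc = np.log(rng.random(I)) < delta
            state.v[acc] = prop[acc]
            mu[acc] = mu_new[acc]
            if rw_sweep:
                window["v"][0] += acc.sum()
                window["v"][1] += I
            accepted["v"] += acc.sum()
            proposed["v"] += I

        # ---- BYM re-split: redraw u | (u + v) ----------------------------
        # The likelihood sees only s = u + v; the split is prior-driven and
        # this exact conditional Gibbs draw keeps tau_u / tau_v mixing.
        if "u" in blocks and "v" in blocks:
            s_sum = state.u + state.v
            for S in color_classes:
                nb_mean = (A[S] @ state.u) / deg[S]
                prec = state.tau_u * deg[S] + state.tau_v
                mean = (state.tau_u * deg[S] * nb_mean + state.tau_v * s_sum[S]) / prec
                state.u[S] = mean + rng.standard_normal(len(S)) / np.sqrt(prec)
            state.v = s_sum - state.u
            if len(graph.islands):
                state.u[graph.islands] = 0.0
                state.v[graph.islands] = s_sum[graph.islands]

        # ---- temporal effect xi ------------------------------------------
        if "xi" in blocks and T >= 2:
            rho_, tx = state.rho, state.tau_xi
            for Tc in (t_even, t_odd):
                if len(Tc) == 0:
                    continue
                xi = state.xi
                mean = np.empty(len(Tc))
                prec = np.empty(len(Tc))
                for k, t in enumerate(Tc):
                    if t == 0:
                        mean[k], prec[k] = rho_ * xi[1], tx
                    elif t == T - 1:
                        mean[k], prec[k] = rho_ * xi[T - 2], tx
                    else:
                        mean[k] = rho_ * (xi[t - 1] + xi[t + 1]) / (1 + rho_**2)
                        prec[k] = tx * (1 + rho_**2)
                if rw_sweep:
                    step = np.exp(log_step["xi"])
                    prop = xi[Tc] + step * rng.standard_normal(len(Tc))
                    prior_delta = -0.5 * prec * (
                        (prop - mean) ** 2 - (xi[Tc] - mean) ** 2
                    )
                else:
                    prop = mean + rng.standard_normal(len(Tc)) / np.sqrt(prec)
                    prior_delta = 0.0  # conditional prior cancels proposal
                ratio = np.exp(prop - xi[Tc])
                mu_new = mu[:, Tc] * ratio[None, :]
                delta = (
                    ws.loglik_cols(mu_new, Tc, r)
                    - ws.loglik_cols(mu[:, Tc], Tc, r)
                    + prior_delta
                )
                acc = np.log(rng.random(len(Tc))) < delta
                state.xi[Tc[acc]] = prop[acc]
                mu[:, Tc[acc]] = mu_new[:, acc]
                if rw_sweep:
                    window["xi"][0] += acc.sum()
                    window["xi"][1] += len(Tc)
                accepted["xi"] += acc.sum()
                proposed["xi"] += len(Tc)

        # ---- space-time interaction nu -----------------------------------
        if "nu" in blocks:
            if rw_sweep:
                step = np.exp(log_step["nu"])
                prop = state.nu + step * rng.standard_normal((I, T))
                prior_delta = -0.5 * state.tau_nu * (prop**2 - state.nu**2)
            else:
                prop = rng.standard_normal((I, T)) / np.sqrt(state.tau_nu)
                prior_delta = 0.0
            mu_new = mu * np.exp(prop - state.nu)
            delta = (
                ws.f_terms(mu_new, ws.y, ws.w, r)
                - ws.f_terms(mu, ws.y, ws.w, r)
                + prior_delta
            )
            acc = np.log(rng.random((I, T))) < delta
            state.nu[acc] = prop[acc]
            mu[acc] = mu_new[acc]
            if rw_sweep:
                window["nu"][0] += acc.sum()
                window["nu"][1] += I * T
            accepted["nu"] += acc.sum()
            proposed["nu"] += I * T

        # ---- intercept alpha ---------------------------------------------
        if "alpha" in blocks:
            step = np.exp(log_step["alpha"])
            dlt = step * rng.standard_normal()
            mu_new = mu * np.exp(dlt)
            delta = ws.loglik_total_kernel(mu_new, r) - ws.loglik_total_kernel(
                mu, r
            )
            proposed["alpha"] += 1
            window["alpha"][1] += 1
            if np.log(rng.random()) < delta:
                state.alpha += dlt
                mu = mu_new
                accepted["alpha"] += 1
                window["alpha"][0] += 1

        # ---- joint field/precision scale moves ------------------------------
        # Rescale a whole random-effect field by gamma while dividing its
        # precision by gamma^2; the Gaussian prior kernel is invariant, so
        # only the likelihood and the weak Gamma hyperprior enter the
        # Metropolis ratio (plus the gamma^(dim-2) Jacobian).  These moves
        # traverse the ridges between a field's magnitude, its precision and
        # the overdispersion (tau_nu vs r especially), which single-site
        # updates cross only by slow diffusion through the funnel.
        if "u" in blocks and "precisions" in blocks and graph.icar_rank > 0:
            g = float(np.exp(np.exp(log_step["u_scale"]) * rng.standard_normal()))
            # scale deviations from component means so the move stays inside
            # the sum-to-zero gauge; the prior dimension is the ICAR rank
            labels = graph.component_labels
            comp_mean = np.bincount(labels, weights=state.u) / np.bincount(labels)
            u_dev = state.u - comp_mean[labels]
            tau_new = state.tau_u / g**2
            mu_new = mu * np.exp((g - 1.0) * u_dev)[:, None]
            delta = (
                ws.loglik_total_kernel(mu_new, r)
                - ws.loglik_total_kernel(mu, r)
                + (a0 - 1.0) * np.log(tau_new / state.tau_u)
                - b0 * (tau_new - state.tau_u)
                + (graph.icar_rank / 2.0) * np.log(tau_new / state.tau_u)
                - 0.5 * (tau_new * g**2 - state.tau_u)
                * icar_pairwise_sum(state.u, graph)
                + (graph.icar_rank - 2.0) * np.log(g)
            )
            window["u_scale"][1] += 1
            if np.log(rng.random()) < delta:
                state.u = comp_mean[labels] + g * u_dev
                state.tau_u = tau_new
                mu = mu_new
                window["u_scale"][0] += 1
        if "nu" in blocks and "precisions" in blocks:
            g = float(np.exp(np.exp(log_step["nu_scale"]) * rng.standard_normal()))
            tau_new = state.tau_nu / g**2
            mu_new = mu * np.exp((g - 1.0) * state.nu)
            delta = (
                ws.loglik_total_kernel(mu_new, r)
                - ws.loglik_total_kernel(mu, r)
                + (a0 - 1.0) * np.log(tau_new / state.tau_nu)
                - b0 * (tau_new - state.tau_nu)
                + (I * T / 2.0) * np.log(tau_new / state.tau_nu)
                - 0.5 * (tau_new * g**2 - state.tau_nu) * float(np.sum(state.nu**2))
                + (I * T - 2.0) * np.log(g)
            )
            window["nu_scale"][1] += 1
            if np.log(rng.random()) < delta:
                state.nu *= g
                state.tau_nu = tau_new
                mu = mu_new
                window["nu_scale"][0] += 1

        # ---- BYM split-scale move -------------------------------------------
        # Rescale the structured deviations by gamma while compensating v so
        # u + v (all the likelihood sees) is unchanged, and keep tau_u in
        # equilibrium.  Only the v prior, the tau_u hyperprior and the
        # Jacobian enter, so the u/v variance allocation mixes quickly.
        if (
            "u" in blocks and "v" in blocks and "precisions" in blocks
            and graph.icar_rank > 0
        ):
            g = float(np.exp(np.exp(log_step["uv_scale"]) * rng.standard_normal()))
            labels = graph.component_labels
            comp_mean = np.bincount(labels, weights=state.u) / np.bincount(labels)
            u_dev = state.u - comp_mean[labels]
            v_new = state.v - (g - 1.0) * u_dev
            tau_new = state.tau_u / g**2
            delta = (
                -0.5 * state.tau_v * float(v_new @ v_new - state.v @ state.v)
                + (a0 - 1.0) * np.log(tau_new / state.tau_u)
                - b0 * (tau_new - state.tau_u)
                + (graph.icar_rank / 2.0) * np.log(tau_new / state.tau_u)
                + (graph.icar_rank - 2.0) * np.log(g)
            )
            window["uv_scale"][1] += 1
            if np.log(rng.random()) < delta:
                state.u = comp_mean[labels] + g * u_dev
                state.v = v_new
                state.tau_u = tau_new
                window["uv_scale"][0] += 1

        # ---- centering moves: trade effect means against alpha ------------
        # alpha + mean(effect) is likelihood-identified; the split is
        # prior-driven.  With a flat prior on alpha each shift c has an
        # exact Gaussian conditional, sampled directly.
        if "alpha" in blocks:
            if "v" in blocks:
                c = rng.normal(
                    float(state.v.mean()), 1.0 / np.sqrt(I * state.tau_v)
                )
                state.v -= c
                state.alpha += c
            if "xi" in blocks and T >= 2:
                rho_, tx = state.rho, state.tau_xi
                d = state.xi[1:] - rho_ * state.xi[:-1]
                A_c = (1.0 - rho_**2) + (T - 1) * (1.0 - rho_) ** 2
                B_c = (1.0 - rho_**2) * state.xi[0] + (1.0 - rho_) * float(
                    d.sum()
                )
                c = rng.normal(B_c / A_c, 1.0 / np.sqrt(tx * A_c))
                state.xi -= c
                state.alpha += c
            if "nu" in blocks:
                c = rng.normal(
                    float(state.nu.mean()), 1.0 / np.sqrt(I * T * state.tau_nu)
                )
                state.nu -= c
                state.alpha += c

        # ---- AR(1) coefficient rho ----------------------------------------
        if "rho" in blocks and T >= 2:
            step = np.exp(log_step["rho"])
            z = np.log((state.rho + 1.0) / (1.0 - state.rho))
            z_new = z + step * rng.standard_normal()
            rho_new = 2.0 * expit(z_new) - 1.0
            delta = (
                ar1_log_density(state.xi, rho_new, state.tau_xi)
                + np.log1p(-(rho_new**2))
                - ar1_log_density(state.xi, state.rho, state.tau_xi)
                - np.log1p(-(state.rho**2))
            )
            proposed["rho"] += 1
            window["rho"][1] += 1
            if np.log(rng.random()) < delta:
                state.rho = float(rho_new)
                accepted["rho"] += 1
                window["rho"][0] += 1

        # ---- precisions (conjugate Gibbs) ----------------------------------
        if "precisions" in blocks:
            state.tau_u = rng.gamma(
                a0 + 0.5 * graph.icar_rank,
                1.0 / (b0 + 0.5 * icar_pairwise_sum(state.u, graph)),
            )
            state.tau_v = rng.gamma(
                a0 + 0.5 * I, 1.0 / (b0 + 0.5 * float(state.v @ state.v))
            )
            if T >= 2:
                state.tau_xi = rng.gamma(
                    a0 + 0.5 * T,
                    1.0 / (b0 + 0.5 * ar1_quad(state.xi, state.rho)),
                )
            state.tau_nu = rng.gamma(
                a0 + 0.5 * I * T,
                1.0 / (b0 + 0.5 * float(np.sum(state.nu**2))),
            )

        # ---- overdispersion r ----------------------------------------------
        if "r" in blocks:
            step = np.exp(log_step["r"])
            w_new = np.log(state.r) + step * rng.standard_normal()
            r_new = float(np.exp(w_new))
            delta = (
                ws.loglik_total_full(mu, r_new)
                - ws.loglik_total_full(mu, state.r)
                + _log_prior_r(r_new, priors)
                - _log_prior_r(state.r, priors)
                + (w_new - np.log(state.r))
            )
            proposed["r"] += 1
            window["r"][1] += 1
            if np.log(rng.random()) < delta:
                state.r = r_new
                accepted["r"] += 1
                window["r"][0] += 1

        # ---- coupled overdispersion ridge move ------------------------------
        # NB overdispersion r and the interaction field nu both absorb
        # extra-Poisson cell noise, leaving a near-flat likelihood ridge
        # between them.  Propose an anti-correlated joint step: shift log r
        # by delta while rescaling nu (with tau_nu kept in equilibrium) by
        # exp(-delta/2 + small orthogonal noise); the centred-Gaussian
        # proposal is symmetric, so the ratio is target plus Jacobians.
        if "r" in blocks and "nu" in blocks and "precisions" in blocks:
            for ridge_mult in ridge_scales:
                s_r = ridge_mult * np.exp(log_step["ridge"])
                d_r = s_r * rng.standard_normal()
                lg = -0.5 * d_r + 0.25 * s_r * rng.standard_normal()
                g = float(np.exp(lg))
                r_new = float(state.r * np.exp(d_r))
                tau_new = state.tau_nu / g**2
                mu_new = mu * np.exp((g - 1.0) * state.nu)
                delta = (
                    ws.loglik_total_full(mu_new, r_new)
                    - ws.loglik_total_full(mu, state.r)
                    + _log_prior_r(r_new, priors)
                    - _log_prior_r(state.r, priors)
                    + d_r  # Jacobian of log-r walk
                    + (a0 - 1.0) * np.log(tau_new / state.tau_nu)
                    - b0 * (tau_new - state.tau_nu)
                    + (I * T / 2.0) * np.log(tau_new / state.tau_nu)
                    + (I * T - 2.0) * lg
                )
                if ridge_mult == 1.0:
                    window["ridge"][1] += 1
                if np.log(rng.random()) < delta:
                    state.r = r_new
                    state.tau_nu = tau_new
                    state.nu *= g
                    mu = mu_new
                    if ridge_mult == 1.0:
                        window["ridge"][0] += 1

        # ---- sum-to-zero recentring ----------------------------------------
        if "u" in blocks:
            if connected:
                m = float(state.u.mean())
                state.u -= m
                state.alpha += m
            else:
                for sel in comp_sets:
                    m = float(state.u[sel].mean())
                    state.u[sel] -= m
                    state.v[sel] += m

        # ---- adaptation (burn-in only) -------------------------------------
        if sweep < cfg.n_burnin and (sweep + 1) % cfg.adapt_interval == 0:
            for k, (na, np_) in window.items():
                if np_ > 0:
                    rate = na / np_
                    log_step[k] += 0.66 * (rate - cfg.target_accept)
                window[k][0] = window[k][1] = 0.0

        # ---- storage --------------------------------------------------------
        if sweep >= cfg.n_burnin and (sweep - cfg.n_burnin) % cfg.thin == 0:
            out["alpha"][kept] = state.alpha
            out["rho"][kept] = state.rho
            out["r"][kept] = state.r
            out["tau_u"][kept] = state.tau_u
            out["tau_v"][kept] = state.tau_v
            out["tau_xi"][kept] = state.tau_xi
            out["tau_nu"][kept] = state.tau_nu
            out["u"][kept] = state.u
            out["v"][kept] = state.v
            out["xi"][kept] = state.xi
            out["nu"][kept] = state.nu
            kept += 1

    rates = {
        k: (accepted[k] / proposed[k]) if proposed[k] else np.nan
        for k in ALL_BLOCKS
    }
    scales = {k: float(np.exp(v)) for k, v in log_step.items()}
    return out, rates, scales


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class NegBinCARModel(BaseEstimator):
    """Bayesian NB spatio-temporal CAR model fitted by Metropolis-within-Gibbs.

    Parameters mirror :class:`McmcConfig`; ``fit`` expects a
    :class:`~anaemap.model.CountPanel` and an
    :class:`~anaemap.graphs.AdjacencyGraph` whose indexing agrees with the
    panel's lexicographic area order.

    Attributes set by :meth:`fit`
    -----------------------------
    chains_ : PosteriorChains
    E_ : ExpectedCounts used as the offset
    summary_ : per-scalar-parameter posterior summary DataFrame
    """

    def __init__(
        self,
        n_chains: int = 2,
        n_iter: int = 71000,
        n_burnin: int = 4000,
        thin: int = 1,
        seed: int = 0,
        adapt_interval: int = 50,
        target_accept: float = 0.44,
        priors: Optional[PriorConfig] = None,
        sample_blocks: Optional[Sequence[str]] = None,
    ):
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.n_burnin = n_burnin
        self.thin = thin
        self.seed = seed
        self.adapt_interval = adapt_interval
        self.target_accept = target_accept
        self.priors = priors
        self.sample_blocks = sample_blocks

    def _config(self) -> McmcConfig:
        return McmcConfig(
            n_chains=self.n_chains,
            n_iter=self.n_iter,
            n_burnin=self.n_burnin,
            thin=self.thin,
            seed=self.seed,
            adapt_interval=self.adapt_interval,
            target_accept=self.target_accept,
        )

    def fit(
        self,
        panel: CountPanel,
        graph: AdjacencyGraph,
        E: Optional[ExpectedCounts] = None,
        initial_states: Optional[Sequence[ModelState]] = None,
    ):
        if graph.n_areas != panel.n_areas:
            raise ValueError(
                f"graph has {graph.n_areas} areas but panel has "
                f"{panel.n_areas}"
            )
        cfg = self._config()
        priors = self.priors if self.priors is not None else PriorConfig()
        if E is None:
            E = compute_expected(panel)
        if initial_states is not None and len(initial_states) != cfg.n_chains:
            raise ValueError("need one initial state per chain")
        seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        ]
        per_chain, rates, scales = [], [], []
        for c in range(cfg.n_chains):
            draws, rate, scale = _run_chain(
                panel,
                E,
                graph,
                priors,
                cfg,
                seeds[c],
                self.sample_blocks,
                initial_states[c] if initial_states is not None else None,
            )
            per_chain.append(draws)
            rates.append(rate)
            scales.append(scale)
        stacked = {
            name: np.stack([d[name] for d in per_chain])
            for name in per_chain[0]
        }
        self.chains_ = PosteriorChains(
            draws=stacked,
            config=cfg,
            seed=cfg.seed,
            acceptance=rates,
            area_ids=panel.area_ids,
            quarter_calendar=panel.quarter_calendar,
            proposal_scales=scales,
        )
        self.E_ = E
        self.graph_ = graph
        self.n_areas_ = panel.n_areas
        self.n_times_ = panel.n_times
        self.summary_ = self.chains_.summary()
        return self

    def predict(self) -> np.ndarray:
        """Posterior-median fitted counts E_it * pi_it (areas x times)."""
        pi = self.chains_.risk_draws()
        return np.median(self.E_.E[None] * pi, axis=0)


def run_mcmc(
    panel: CountPanel,
    E: Optional[ExpectedCounts],
    graph: AdjacencyGraph,
    priors: Optional[PriorConfig] = None,
    config: Optional[McmcConfig] = None,
    sample_blocks: Optional[Sequence[str]] = None,
    initial_states: Optional[Sequence[ModelState]] = None,
) -> PosteriorChains:
    """Functional wrapper over :class:`NegBinCARModel`."""
    cfg = config if config is not None else McmcConfig()
    model = NegBinCARModel(
        n_chains=cfg.n_chains,
        n_iter=cfg.n_iter,
        n_burnin=cfg.n_burnin,
        thin=cfg.thin,
        seed=cfg.seed,
        adapt_interval=cfg.adapt_interval,
        target_accept=cfg.target_accept,
        priors=priors,
        sample_blocks=sample_blocks,
    )
    model.fit(panel, graph, E=E, initial_states=initial_states)
    return model.chains_
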