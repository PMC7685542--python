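"""Convergence diagnostics and holdout predictive validation.

Convergence is assessed with the Gelman–Rubin potential scale reduction
factor.  The default is the modern *split* form (each chain cut in half
before comparing between- and within-sequence variance), which is more
conservative than the classic two-chain statistic; the classic form is
also exposed for comparability with WinBUGS-era reporting.  Effective
sample size uses Geyer's initial-positive-sequence truncation of the
autocorrelation sum.

Predictive validation follows a single-refit holdout protocol: a random
subset of observed cells is masked, the model is refitted once on the
reduced panel, and held-out counts are compared with their posterior
predictive medians by correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .graphs import AdjacencyGraph
from .mcmc import (
    McmcConfig,
    NegBinCARModel,
    PosteriorChains,
    SCALAR_PARAMS,
)
from .model import CountPanel, ExpectedCounts, PriorConfig, compute_expected


# ---------------------------------------------------------------------------
# Gelman-Rubin
# ---------------------------------------------------------------------------


def _psrf(seqs: np.ndarray) -> float:
    """PSRF over an (m, n) array of sequences."""
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    W = float(seqs.var(axis=1, ddof=1).mean())
    B_over_n = float(means.var(ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def gelman_rubin(
    chains: Union[np.ndarray, PosteriorChains],
    params: Optional[Sequence[str]] = None,
    split: bool = True,
):
    """Potential scale reduction factor.

    With an (n_chains, n_draws) array input, returns a float.  With a
    :class:`PosteriorChains` input, returns a dict mapping each selected
    scalar parameter (default: all) to its PSRF.
    """
    if isinstance(chains, PosteriorChains):
        names = list(params) if params is not None else list(SCALAR_PARAMS)
        return {
            name: gelman_rubin(chains.get(name), split=split) for name in names
        }
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected an (n_chains, n_draws) array")
    m, n = arr.shape
    if m < 2:
        raise ValueError(
            "Gelman-Rubin needs at least two chains; rerun with n_chains >= 2"
        )
    if split:
        half = n // 2
        seqs = np.concatenate([arr[:, :half], arr[:, half : 2 * half]], axis=0)
    else:
        seqs = arr
    return _psrf(seqs)


def gelman_rubin_classic(chains, params=None):
    """The unsplit (original two-chain) form of the statistic."""
    return gelman_rubin(chains, params=params, split=False)


# ---------------------------------------------------------------------------
# effective sample size
# ---------------------------------------------------------------------------


def effective_sample_size(draws: np.ndarray) -> float:
    """ESS by Geyer's initial positive sequence estimator.

    Returns NaN (with a warning) for a constant chain, where the
    autocorrelation time is undefined.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 draws for an ESS estimate")
    if np.var(x) == 0.0:
        warnings.warn("constant chain: ESS undefined", stacklevel=2)
        return float("nan")
    from statsmodels.tsa.stattools import acovf

    acov = acovf(x, fft=True, nlag=n - 1)
    rho = acov / acov[0]
    # pair consecutive autocorrelations; stop at the first non-positive pair
    tau = 0.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if gamma <= 0.0:
            break
        tau += gamma
        m += 1
    tau = max(2.0 * tau - 1.0, 1.0 / n)
    return float(n / tau)


# ---------------------------------------------------------------------------
# holdout validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    """Held-out cells, their posterior predictive summaries and correlations."""

    held_out_cells: list[tuple[int, int]]
    observed: np.ndarray
    predicted: np.ndarray
    predicted_lo: np.ndarray
    predicted_hi: np.ndarray
    correlation: float
    spearman: float
    seed: int

    @property
    def n_holdout(self) -> int:
        return len(self.held_out_cells)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "area_index": [c[0] for c in self.held_out_cells],
                "time_index": [c[1] for c in self.held_out_cells],
                "observed": self.observed,
                "predicted_median": self.predicted,
                "predicted_q2.5": self.predicted_lo,
                "predicted_q97.5": self.predicted_hi,
            }
        )

    def scatterplot(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(self.observed, self.predicted, s=12, alpha=0.7)
        lim = max(self.observed.max(), self.predicted.max()) * 1.05
        ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--")
        ax.set_xlabel("held-out observed count")
        ax.set_ylabel("posterior predictive median")
        ax.set_title(f"holdout validation (r = {self.correlation:.3f})")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def sample_holdout_cells(
    panel: CountPanel, n_holdout: int, seed: int
) -> list[tuple[int, int]]:
    """Uniform sample (without replacement) of observed cells."""
    obs = np.argwhere(panel.observed_mask)
    if n_holdout >= len(obs):
        raise ValueError(
            f"n_holdout={n_holdout} must be smaller than the "
            f"{len(obs)} observed cells"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(obs), size=n_holdout, replace=False)
    return [tuple(map(int, obs[k])) for k in pick]


def mask_cells(panel: CountPanel, cells: Sequence[tuple[int, int]]) -> CountPanel:
    """Return a copy of the panel with the given case counts masked."""
    cases = panel.cases.copy()
    for i, t in cells:
        cases[i, t] = np.nan
    return CountPanel(
        panel.area_ids,
        cases,
        panel.denominators.copy(),
        panel.quarter_calendar,
        panel.zone,
    )


def holdout_validate(
    panel: CountPanel,
    E: Optional[ExpectedCounts],
    graph: AdjacencyGraph,
    priors: Optional[PriorConfig] = None,
    config: Optional[McmcConfig] = None,
    n_holdout: int = 500,
    seed: int = 0,
) -> ValidationReport:
    """Single-refit holdout validation of posterior predictive counts.

    Held-out case counts are masked before the offset is standardised and
    before fitting, so no information leaks into the refit.  If ``E`` is
    given it is used as-is (externally supplied offsets); otherwise the
    offset is recomputed from the masked panel.
    """
    cells = sample_holdout_cells(panel, n_holdout, seed)
    masked = mask_cells(panel, cells)
    if E is None:
        E = compute_expected(masked)
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
    )
    model.fit(masked, graph, E=E)

    pi = model.chains_.risk_draws()  # (S, I, T)
    rows = np.array([c[0] for c in cells])
    cols = np.array([c[1] for c in cells])
    mu = E.E[rows, cols][None, :] * pi[:, rows, cols]  # (S, n_holdout)
    r = model.chains_.stacked("r")[:, None]
    rng = np.random.default_rng(seed + 1)
    lam = rng.gamma(shape=1.0 / r, scale=r * mu)
    y_rep = rng.poisson(lam)  # NB via gamma-Poisson mixture
    pred = np.median(y_rep, axis=0)
    lo = np.quantile(y_rep, 0.025, axis=0)
    hi = np.quantile(y_rep, 0.975, axis=0)
    observed = panel.cases[rows, cols]
    if np.var(observed) > 0 and np.var(pred) > 0:
        pearson = float(stats.pearsonr(observed, pred).statistic)
        spear = float(stats.spearmanr(observed, pred).statistic)
    else:
        pearson = spear = float("nan")
    return ValidationReport(
        held_out_cells=cells,
        observed=observed,
        predicted=pred,
        predicted_lo=lo,
        predicted_hi=hi,
        correlation=pearson,
        spearman=spear,
        seed=seed,
    )
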