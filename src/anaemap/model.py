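"""Likelihood, linear predictor, priors and derived quantities.

The observation model is a negative binomial on quarterly case counts,

    Hb_it | pi_it ~ NegBin(mean = E_it * pi_it, overdispersion r),

with variance ``mu (1 + r mu)`` so the Poisson is recovered as r -> 0.
The log relative risk decomposes as

    log pi_it = alpha + u_i + v_i + xi_t + nu_it,

i.e. a BYM convolution (structured ICAR ``u`` plus unstructured iid ``v``),
a stationary AR(1) quarter effect ``xi`` and an iid space-time interaction
``nu``.  Expected counts ``E_it`` come from internal standardisation of the
denominators (new antenatal clients).  Everything here is a pure function
shared by the sampler, the reporting layer and the test oracles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountPanel:
    """Area x quarter panel of observed cases and denominators.

    ``cases`` and ``denominators`` are float matrices with NaN marking a
    missing cell; a cell is *observed* only when both are present.  Areas
    are indexed lexicographically by ``area_ids`` and times chronologically
    by ``quarter_calendar`` (a tuple of ``(year, quarter)`` pairs).
    """

    area_ids: tuple[str, ...]
    cases: np.ndarray
    denominators: np.ndarray
    quarter_calendar: tuple[tuple[int, int], ...]
    zone: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        I, T = len(self.area_ids), len(self.quarter_calendar)
        if self.cases.shape != (I, T) or self.denominators.shape != (I, T):
            raise ValueError(
                f"cases/denominators must be {I}x{T} matrices, got "
                f"{self.cases.shape} and {self.denominators.shape}"
            )
        if self.zone is not None and len(self.zone) != I:
            raise ValueError("zone must provide one label per area")
        obs = self.observed_mask
        with np.errstate(invalid="ignore"):
            bad = obs & (self.cases > self.denominators)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} cell(s) report more cases than new clients; "
                "kept as-is (routine data may exceed its denominator)",
                stacklevel=2,
            )

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_times(self) -> int:
        return len(self.quarter_calendar)

    @property
    def observed_mask(self) -> np.ndarray:
        return ~(np.isnan(self.cases) | np.isnan(self.denominators))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted({y for y, _ in self.quarter_calendar}))

    def time_indices_for_year(self, year: int) -> np.ndarray:
        idx = [t for t, (y, _) in enumerate(self.quarter_calendar) if y == year]
        if not idx:
            raise ValueError(f"year {year} not present in the panel")
        return np.asarray(idx, dtype=np.intp)

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for i, aid in enumerate(self.area_ids):
            for t, (year, quarter) in enumerate(self.quarter_calendar):
                rows.append(
                    {
                        "area_id": aid,
                        "year": year,
                        "quarter": quarter,
                        "cases": self.cases[i, t],
                        "new_clients": self.denominators[i, t],
                        "zone": self.zone[i] if self.zone is not None else "",
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df) -> "CountPanel":
        """Build a panel from long-format records (area_id, year, quarter,
        cases, new_clients[, zone]); missing rows become missing cells."""
        required = {"area_id", "year", "quarter", "cases", "new_clients"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel records lack columns: {sorted(missing)}")
        area_ids = tuple(sorted(df["area_id"].astype(str).unique()))
        calendar = tuple(
            sorted({(int(y), int(q)) for y, q in zip(df["year"], df["quarter"])})
        )
        a_index = {a: i for i, a in enumerate(area_ids)}
        t_index = {yq: t for t, yq in enumerate(calendar)}
        I, T = len(area_ids), len(calendar)
        cases = np.full((I, T), np.nan)
        denoms = np.full((I, T), np.nan)
        zones: dict[str, str] = {}
        for rec in df.itertuples(index=False):
            i = a_index[str(rec.area_id)]
            t = t_index[(int(rec.year), int(rec.quarter))]
            cases[i, t] = rec.cases
            denoms[i, t] = rec.new_clients
            if hasattr(rec, "zone") and isinstance(rec.zone, str) and rec.zone:
                zones[str(rec.area_id)] = rec.zone
        zone = (
            tuple(zones.get(a, "") for a in area_ids) if zones else None
        )
        if zone is not None and any(z == "" for z in zone):
            absent = [a for a, z in zip(area_ids, zone) if z == ""]
            raise ValueError(f"areas missing a zone label: {absent}")
        return cls(area_ids, cases, denoms, calendar, zone)


@dataclass(frozen=True)
class ExpectedCounts:
    """Internally standardised expected counts E_it (NaN where undefined)."""

    E: np.ndarray


@dataclass
class ModelState:
    """One configuration of all model parameters (one MCMC draw)."""

    alpha: float
    u: np.ndarray
    v: np.ndarray
    xi: np.ndarray
    nu: np.ndarray
    rho: float
    tau_u: float
    tau_v: float
    tau_xi: float
    tau_nu: float
    r: float

    def __post_init__(self) -> None:
        for name in ("tau_u", "tau_v", "tau_xi", "tau_nu", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")

    def copy(self) -> "ModelState":
        return replace(
            self,
            u=self.u.copy(),
            v=self.v.copy(),
            xi=self.xi.copy(),
            nu=self.nu.copy(),
        )


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the weakly-informative priors.

    All four precisions and the inverse overdispersion 1/r get
    Gamma(shape, rate) priors; the intercept is flat; any regression
    coefficient (none in the default model) would get Normal(0, sd).
    ``rho`` is uniform on (-1, 1).
    """

    gamma_shape: float = 0.5
    gamma_rate: float = 0.0005
    normal_sd_coeff: float = 10.0

    def __post_init__(self) -> None:
        if min(self.gamma_shape, self.gamma_rate, self.normal_sd_coeff) <= 0:
            raise ValueError("all prior hyperparameters must be positive")


# ---------------------------------------------------------------------------
# densities and transforms
# ---------------------------------------------------------------------------


def nb_log_pmf(y, mu, r):
    """Negative-binomial log pmf with mean ``mu`` and variance ``mu(1+r mu)``.

    The size parameter is 1/r; as r -> 0 the pmf converges to Poisson(mu).
    Vectorised over broadcastable ``y``, ``mu``, ``r``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if np.any(mu <= 0) or np.any(r <= 0):
        raise ValueError("mu and r must be positive")
    n = 1.0 / r
    # n log p = -log1p(r mu)/r and log(1-p) = log(r mu) - log1p(r mu);
    # written this way the Poisson limit r -> 0 stays accurate.
    out = (
        gammaln(y + n)
        - gammaln(n)
        - gammaln(y + 1.0)
        - np.log1p(r * mu) / r
        + y * (np.log(r * mu) - np.log1p(r * mu))
    )
    return out if out.shape else float(out)


def relative_risk(state: ModelState, i: int, t: int) -> float:
    """pi_it = exp(alpha + u_i + v_i + xi_t + nu_it)."""
    return float(
        np.exp(
            state.alpha
            + state.u[i]
            + state.v[i]
            + state.xi[t]
            + state.nu[i, t]
        )
    )


def relative_risk_matrix(state: ModelState) -> np.ndarray:
    """All pi_it at once (areas x times)."""
    return np.exp(
        state.alpha
        + state.u[:, None]
        + state.v[:, None]
        + state.xi[None, :]
        + state.nu
    )


def compute_expected(panel: CountPanel) -> ExpectedCounts:
    """Expected counts by global internal standardisation.

    E_it = N_it * (sum cases / sum N), with the crude rate taken over the
    observed cells; E is filled wherever a denominator is present (so that
    cells whose case count is masked, e.g. holdout cells, still carry an
    offset) and NaN where the denominator is missing.
    """
    obs = panel.observed_mask
    if not obs.any():
        raise ValueError("panel has no observed cells")
    N_obs = panel.denominators[obs]
    if np.any(N_obs <= 0):
        raise ValueError("denominators must be positive on observed cells")
    rate = float(panel.cases[obs].sum() / N_obs.sum())
    with np.errstate(invalid="ignore"):
        ok = ~np.isnan(panel.denominators) & (panel.denominators > 0)
    E = np.where(ok, panel.denominators * rate, np.nan)
    return ExpectedCounts(E=E)


def panel_log_likelihood(
    panel: CountPanel, E: ExpectedCounts, state: ModelState
) -> float:
    """Sum of NB log pmfs over observed cells; missing cells contribute 0."""
    obs = panel.observed_mask
    if not obs.any():
        return 0.0
    mu = E.E[obs] * relative_risk_matrix(state)[obs]
    return float(np.sum(nb_log_pmf(panel.cases[obs], mu, state.r)))


def ar1_log_density(xi: np.ndarray, rho: float, tau_xi: float) -> float:
    """Stationary AR(1) log density of the quarter effects.

    xi_1 ~ N(0, 1/(tau (1 - rho^2))), xi_t | xi_{t-1} ~ N(rho xi_{t-1}, 1/tau).
    """
    xi = np.asarray(xi, dtype=float)
    T = xi.shape[0]
    if T < 2:
        raise ValueError("AR(1) effect needs at least two time points")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    if tau_xi <= 0:
        raise ValueError("tau_xi must be positive")
    quad = (1.0 - rho**2) * xi[0] ** 2 + float(
        np.sum((xi[1:] - rho * xi[:-1]) ** 2)
    )
    return float(
        0.5 * T * np.log(tau_xi)
        + 0.5 * np.log1p(-(rho**2))
        - 0.5 * T * np.log(2.0 * np.pi)
        - 0.5 * tau_xi * quad
    )


def iid_normal_log_density(x: np.ndarray, tau: float) -> float:
    """Log density of iid N(0, 1/tau) entries (used for v and nu)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    return float(
        0.5 * n * (np.log(tau) - np.log(2.0 * np.pi)) - 0.5 * tau * np.sum(x**2)
    )


def prevalence(
    panel: CountPanel, E: ExpectedCounts, state: ModelState, i: int, t: int
) -> float:
    """Modelled prevalence E_it * pi_it / N_it for one cell.

    Values above 1 are possible under the count model and are returned
    as-is with a warning rather than raising.
    """
    N = panel.denominators[i, t]
    if not np.isfinite(N) or N <= 0:
        raise ValueError(f"cell ({i},{t}) has no positive denominator")
    p = float(E.E[i, t] * relative_risk(state, i, t) / N)
    if p > 1.0:
        warnings.warn(
            f"modelled prevalence {p:.3f} exceeds 1 at cell ({i},{t})",
            stacklevel=2,
        )
    return p
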