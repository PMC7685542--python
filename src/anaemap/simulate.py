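"""Synthetic count panels with the exact generative structure of the model.

The generator emulates a routine health-information panel: a lattice of
areas observed over consecutive quarters, log-normal facility volumes as
denominators, and NB-overdispersed counts whose log relative risk is the
sum of an ICAR-structured spatial field, an iid spatial field, a
stationary AR(1) quarter effect and an iid space-time interaction.  Every
replicate returns the ground-truth parameter state so that recovery,
dispersion and classification behaviour can be tested against known
values.

Realised effect vectors are centred (u exactly sum-to-zero per component
by construction; v, xi and nu recentred to zero mean) so that the global
intercept of the generating process is identified and recoverable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .graphs import AdjacencyGraph, graph_from_edge_list
from .model import CountPanel, ExpectedCounts, ModelState

ZONE_LABELS = ("Coast", "Highland", "Lake", "Low risk", "Seasonal")


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and panel geometry for synthetic data.

    Defaults give the reduced desk-scale study (30 areas x 8 quarters);
    :meth:`paper_scale` switches to the full 290 x 16 geometry.  The
    baseline crude rate of 0.15 reflects a mid-teens anaemia prevalence
    among new antenatal clients; denominators follow
    LogNormal(log 800, 0.6), echoing facility-volume heterogeneity.
    """

    n_areas: int = 30
    n_times: int = 8
    grid_shape: Optional[tuple[int, int]] = None
    alpha: float = 0.2
    tau_u: float = 4.0
    tau_v: float = 4.0
    tau_xi: float = 4.0
    tau_nu: float = 4.0
    rho: float = 0.6
    r: float = 0.3
    base_rate: float = 0.15
    denom_median: float = 800.0
    denom_sigma: float = 0.6
    missing_rate: float = 0.0
    start_year: int = 2016
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau_u", "tau_v", "tau_xi", "tau_nu", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_areas < 2 or self.n_times < 2:
            raise ValueError("need at least 2 areas and 2 quarters")
        if self.grid_shape is not None:
            rows, cols = self.grid_shape
            if rows * cols < self.n_areas:
                raise ValueError(
                    f"grid {rows}x{cols} cannot hold {self.n_areas} areas"
                )

    @classmethod
    def paper_scale(cls, **overrides) -> "GeneratorConfig":
        base = dict(n_areas=290, n_times=16)
        base.update(overrides)
        return cls(**base)


def lattice_graph(
    n_areas: int, grid_shape: Optional[tuple[int, int]] = None
) -> AdjacencyGraph:
    """Rook-contiguity lattice over ``n_areas`` cells (row-major order)."""
    if grid_shape is None:
        rows = int(math.floor(math.sqrt(n_areas)))
        cols = int(math.ceil(n_areas / rows))
        grid_shape = (rows, cols)
    rows, cols = grid_shape
    pairs = []
    for k in range(n_areas):
        ri, ci = divmod(k, cols)
        if ci + 1 < cols and k + 1 < n_areas and (k + 1) // cols == ri:
            pairs.append((k, k + 1))
        if ri + 1 < rows and k + cols < n_areas:
            pairs.append((k, k + cols))
    return graph_from_edge_list(pairs, n_areas)


def sample_icar(
    graph: AdjacencyGraph, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact draw from the sum-to-zero-constrained ICAR distribution.

    Eigen-decomposes the graph Laplacian and samples along the non-null
    eigenvectors with variance 1/(tau * eigenvalue); islands get 0.
    """
    L = np.diag(graph.degrees.astype(float)) - graph.adjacency.toarray()
    w, Q = np.linalg.eigh(L)
    pos = w > 1e-9
    z = rng.standard_normal(int(pos.sum()))
    u = Q[:, pos] @ (z / np.sqrt(tau * w[pos]))
    u[graph.islands] = 0.0
    return u


def sample_ar1(
    n: int, rho: float, tau: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1) path with marginal variance 1/(tau (1 - rho^2))."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, 1.0 / math.sqrt(tau * (1.0 - rho**2)))
    eps = rng.normal(0.0, 1.0 / math.sqrt(tau), n - 1)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def draw_nb_counts(
    mu: np.ndarray, r: float, rng: np.random.Generator
) -> np.ndarray:
    """NB(mean mu, overdispersion r) via the gamma-Poisson mixture.

    Stable for arbitrarily small r (Poisson limit).
    """
    lam = rng.gamma(shape=1.0 / r, scale=r * np.asarray(mu, dtype=float))
    return rng.poisson(lam).astype(float)


def _quarter_calendar(n_times: int, start_year: int):
    return tuple(
        (start_year + t // 4, t % 4 + 1) for t in range(n_times)
    )


def _zone_assignment(n_areas: int) -> tuple[str, ...]:
    """Five contiguous blocks of areas (in lattice row-major order)."""
    blocks = np.array_split(np.arange(n_areas), len(ZONE_LABELS))
    zone = [""] * n_areas
    for label, block in zip(ZONE_LABELS, blocks):
        for k in block:
            zone[k] = label
    return tuple(zone)


def true_expected(panel: CountPanel, config: GeneratorConfig) -> ExpectedCounts:
    """The generator's own offset, base_rate * N (known ground truth)."""
    with np.errstate(invalid="ignore"):
        ok = np.isfinite(panel.denominators) & (panel.denominators > 0)
    return ExpectedCounts(
        E=np.where(ok, config.base_rate * panel.denominators, np.nan)
    )


def generate_panel(
    config: GeneratorConfig,
) -> tuple[CountPanel, ModelState, AdjacencyGraph]:
    """Simulate one panel; returns (panel, ground-truth state, graph)."""
    rng = np.random.default_rng(config.seed)
    graph = lattice_graph(config.n_areas, config.grid_shape)
    I, T = config.n_areas, config.n_times

    u = sample_icar(graph, config.tau_u, rng)
    v = rng.normal(0.0, 1.0 / math.sqrt(config.tau_v), I)
    v -= v.mean()
    xi = sample_ar1(T, config.rho, config.tau_xi, rng)
    xi -= xi.mean()
    nu = rng.normal(0.0, 1.0 / math.sqrt(config.tau_nu), (I, T))
    nu -= nu.mean()

    N = np.ceil(
        rng.lognormal(math.log(config.denom_median), config.denom_sigma, (I, T))
    )
    N = np.maximum(N, 20.0)

    pi = np.exp(config.alpha + u[:, None] + v[:, None] + xi[None, :] + nu)
    mu = config.base_rate * N * pi
    cases = draw_nb_counts(mu, config.r, rng)

    if config.missing_rate > 0:
        miss = rng.random((I, T)) < config.missing_rate
        cases = np.where(miss, np.nan, cases)

    width = max(3, len(str(I - 1)))
    area_ids = tuple(f"a{k:0{width}d}" for k in range(I))
    panel = CountPanel(
        area_ids=area_ids,
        cases=cases,
        denominators=N,
        quarter_calendar=_quarter_calendar(T, config.start_year),
        zone=_zone_assignment(I),
    )
    truth = ModelState(
        alpha=config.alpha,
        u=u,
        v=v,
        xi=xi,
        nu=nu,
        rho=config.rho,
        tau_u=config.tau_u,
        tau_v=config.tau_v,
        tau_xi=config.tau_xi,
        tau_nu=config.tau_nu,
        r=config.r,
    )
    return panel, truth, graph


def generate_severity_fixture(
    targets,
    denominator: int = 1000,
    n_times: int = 4,
    start_year: int = 2016,
    zone: Optional[tuple[str, ...]] = None,
) -> CountPanel:
    """Deterministic panel whose per-area crude prevalence hits ``targets``.

    Each area gets constant cases = round(target * N) in every quarter; a
    target that is not attainable with integer counts is replaced by the
    nearest attainable value with a warning.
    """
    targets = np.asarray(targets, dtype=float)
    if np.any((targets < 0) | (targets > 1)):
        raise ValueError("targets must lie in [0, 1]")
    I = len(targets)
    cases_per_cell = np.round(targets * denominator)
    achieved = cases_per_cell / denominator
    off = ~np.isclose(achieved, targets, atol=1e-12)
    if off.any():
        warnings.warn(
            f"{int(off.sum())} target(s) not attainable with N={denominator}; "
            "using nearest attainable prevalence",
            stacklevel=2,
        )
    width = max(3, len(str(I - 1)))
    area_ids = tuple(f"a{k:0{width}d}" for k in range(I))
    cases = np.tile(cases_per_cell[:, None], (1, n_times)).astype(float)
    denoms = np.full((I, n_times), float(denominator))
    return CountPanel(
        area_ids=area_ids,
        cases=cases,
        denominators=denoms,
        quarter_calendar=_quarter_calendar(n_times, start_year),
        zone=zone,
    )
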