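# Methods

## Model

`anaemap` fits a Bayesian hierarchical negative-binomial spatio-temporal
model to an area × quarter panel of routinely reported case counts
(maternal anaemia cases among new antenatal clients, in the motivating
application).  For area `i` and quarter `t`,

    y_it | pi_it ~ NegBin(mean = E_it * pi_it, overdispersion r)
    log pi_it    = alpha + u_i + v_i + xi_t + nu_it

with variance `mu (1 + r mu)`, so the Poisson is the `r -> 0` limit and the
NB size parameter is `1/r`.  The components are

* `E_it` — expected counts by global internal standardisation:
  `E_it = N_it * (sum y / sum N)` over observed cells, where `N_it` is the
  denominator (new clients).  Standardisation is global rather than
  per-quarter so that the temporal signal stays in `xi`.
* `u` — spatially structured effect with an intrinsic CAR (ICAR) prior:
  the joint kernel penalises `tau_u/2 * sum_{i~j} (u_i - u_j)^2` over
  contiguity edges and is flat along per-component constants; a sum-to-zero
  constraint per connected component identifies the intercept.
* `v` — unstructured iid `N(0, 1/tau_v)` effect; `u + v` is the classic
  BYM convolution.
* `xi` — stationary AR(1) quarter effect: `xi_1 ~ N(0, 1/(tau_xi (1-rho^2)))`,
  `xi_t | xi_{t-1} ~ N(rho xi_{t-1}, 1/tau_xi)`, `|rho| < 1`.  The effect is
  indexed over all quarters (not four seasonal levels); the quarter-of-year
  mapping is kept only for reporting.
* `nu` — iid `N(0, 1/tau_nu)` space-time interaction (unstructured,
  Knorr-Held type I).

Priors: flat on `alpha`; `Gamma(0.5, 0.0005)` on each precision and on
`1/r` (the conventional weakly-informative disease-mapping choice, here the
package default and overridable through `PriorConfig`); uniform on
`rho in (-1, 1)`; `N(0, 10^2)` is reserved for regression coefficients,
none of which exist in the default covariate-free model.

Counts may exceed their denominators in routine data; this is kept (with a
warning), never truncated.  A cell is observed only when both the count and
the denominator are present; missing cells contribute nothing to the
likelihood.

## Sampler

`NegBinCARModel` (a scikit-learn-style estimator; `run_mcmc` is a thin
functional wrapper) runs Metropolis-within-Gibbs chains.  Each sweep:

1. `u`: single-site updates vectorised over graph-colour classes, proposing
   from the ICAR full conditional `N(mean of neighbours, 1/(tau_u m_i))` so
   the Metropolis correction is the NB likelihood ratio alone.
2. `v`, `nu`, `xi`: elementwise (or time-parity-wise for `xi`) Metropolis.
   Sweeps alternate between an adaptive random walk and an independence
   proposal from the conditional prior; the mixture keeps the
   precision/effect funnel mixing when the likelihood is weak.
3. `alpha`: scalar random walk. `rho`: random walk on `logit((rho+1)/2)`
   with the Jacobian correction. `r`: random walk on `log r`.
4. Precisions: conjugate Gibbs, e.g.
   `tau_u ~ Gamma(a + rank/2, b + S(u)/2)` with `S(u)` the ICAR quadratic
   form and `rank` = non-island areas minus connected components.
5. Exact likelihood-invariant Gibbs moves along the model's soft
   non-identifiabilities: redraw of `u` given the BYM sum `u + v`; shifts of
   the means of `v`, `xi`, `nu` into the flat-prior intercept.
6. Joint field/precision scale moves (`u` and `nu` rescaled by `gamma`
   while their precision is divided by `gamma^2`, Metropolis-corrected with
   the `gamma^(dim-2)` Jacobian), a BYM split-scale move that reallocates
   variance between `u` and `v` without touching the likelihood, and a
   coupled ridge move that changes `log r` and the `nu` field scale in one
   anti-correlated step.  One ridge repetition per sweep uses a fixed wide
   step so the chain can hop between dispersion-allocation modes.
7. Sum-to-zero recentring of `u` per component.  On a connected graph the
   compensation goes into the flat-prior intercept, which leaves the
   posterior exactly invariant; on a multi-component graph each component
   mean is moved into `v` instead, which preserves the likelihood but
   perturbs the `v` prior — acceptable for the package's connected default
   lattices and flagged here as an approximation otherwise.

Proposal scales adapt toward a 0.44 acceptance rate during burn-in only;
the post-burn-in kernel is fixed, preserving detailed balance.  Runs are
bit-reproducible given (seed, config, inputs); per-chain seeds are spawned
from the user seed.  Initial states follow a fixed recipe (intercept at the
log ratio of observed to expected totals — zero under internal
standardisation — small Gaussian jitter on all effects, unit precisions,
`rho = 0`, `r = 0.5`); a non-finite initial log posterior raises an
initialisation error with a diagnostic summary.

Islands (areas without neighbours) have their structured effect fixed at
zero — the unstructured `v` absorbs their variation — and
`icar_full_conditional` raises `IslandError` for them.

Protocol defaults are the full analysis configuration (2 chains × 71,000
iterations, 4,000 burn-in).  All development, testing and the shipped
synthetic studies use the documented desk preset
`McmcConfig.desk_scale()` — 2 × 6,000 iterations, 1,000 burn-in — on
30-area × 8-quarter panels; these sizes are the package's own choice of
routine scale and can be raised freely.

## Synthetic data

`generate_panel` simulates from exactly the model above on a rook-contiguity
lattice: `u` sampled exactly from the constrained ICAR distribution by
eigen-decomposition of the graph Laplacian (exact up to a few hundred
areas), `xi` from the stationary AR(1), `v`/`nu` iid normal, denominators
`ceil(LogNormal(log 800, 0.6))` floored at 20 (facility-volume
heterogeneity; arbitrary but documented and configurable), counts via the
gamma-Poisson mixture (stable for any `r`), and zone labels as five
contiguous blocks.  Default truth: 30 areas × 8 quarters, `alpha = 0.2`,
`rho = 0.6`, `r = 0.3`, all precisions 4, baseline crude rate 0.15 (a
mid-teens prevalence among new clients, matching the scale of the
motivating surveillance data); `GeneratorConfig.paper_scale()` switches to
the full 290 × 16 geometry.

Two deliberate choices make ground truth recoverable in simulation studies:

* Realised effect vectors are centred (`u` is sum-to-zero by construction;
  `v`, `xi`, `nu` are recentred to zero mean), so the generating intercept
  is identified rather than confounded with the realised effect means.
* Recovery studies must fit with the generator's true offset
  (`true_expected`, i.e. `base_rate * N`).  Internal standardisation
  recomputed from realised cases absorbs the realised mean relative risk
  into the offset and shifts the intercept by
  `-log(weighted mean of exp(effects))` — about `-sigma_total^2/2` — making
  the nominal intercept unrecoverable by construction.  The pipeline's own
  standardised offset remains the default everywhere else.

What the generator does **not** emulate: reporting-completeness artefacts
(strike-period under-reporting, zero-vs-missing ambiguity), covariate
structure, irregular geography (unless polygons are supplied), or
denominator drift.  Passing synthetic tests therefore certify the
machinery — likelihood, priors, sampler, diagnostics, reporting — on data
that satisfy the model's assumptions, not the model's adequacy for any
real surveillance system.

## Known limitation: dispersion-allocation bimodality

The NB overdispersion `r` and the iid interaction field `nu` both absorb
cell-level extra-Poisson noise, and at routine desk scale (240 cells) the
likelihood barely separates them (a gamma-mixture and a lognormal-mixture
of comparable variance are nearly indistinguishable).  Because the default
`Gamma(0.5, 0.0005)` priors on `tau_nu` and `1/r` each concentrate mass at
"this channel contributes nothing", the joint posterior is bimodal: one
mode puts the dispersion in `r`, the other in `nu`.  Long, well-mixed
chains on some synthetic replicates settle decisively in one corner and
exclude a mid-ridge truth such as `(r = 0.3, tau_nu = 4)`.  Consequences:

* fixed-truth 95%-interval coverage for `r`, `tau_nu` (and, more mildly,
  the BYM pair `tau_u`/`tau_v`, which share the same phenomenon along the
  `u + v` ridge) falls well short of nominal at this scale — roughly 60%
  for the dispersion pair in the shipped 20-replicate study — while
  `alpha` and `rho` remain essentially calibrated;
* inference about *which* channel carries the dispersion should not be
  trusted at this scale; the fitted risks `pi_it`, which depend on the
  identified sums, are unaffected.

This is a property of the model-plus-prior at small scale, not of the
sampler: the no-data prior-recovery check (precision marginals reproduce
their Gamma prior, KS-tested against an exact conjugate-Gibbs oracle at
calibrated thinning) certifies the kernel, and the wide-step ridge move
exists precisely to let chains visit both modes.

## Diagnostics and validation

* Gelman–Rubin: split form by default (each chain halved before comparing
  between/within variance — strictly more conservative); the classic
  unsplit statistic is exposed for comparability with older reporting.
* ESS: Geyer initial-positive-sequence estimator on the autocovariance;
  constant chains return NaN with a warning.
* Holdout validation: a seeded uniform sample of observed cells is masked,
  the offset is recomputed from the masked panel (no leakage), the model is
  refitted once, and each held-out count is compared with the median of its
  posterior predictive NB draws; Pearson (headline) and Spearman
  correlations are reported with a scatterplot export.  The full protocol
  masks 500 cells; the desk preset masks 50.

## Classification and reporting

WHO severity grades on prevalence: `< 5%` normal, `5–19.9%` mild,
`20–39.9%` moderate, `>= 40%` severe, with half-open boundaries exactly at
0.05 / 0.20 / 0.40.  Area-level prevalence for a year is pooled —
`sum_t E pi / sum_t N` over the year's quarters — so quarters are weighted
by client volume.  Classes are assigned *per posterior draw* and the class
proportions summarised over draws (median, 2.5th/97.5th percentiles), which
is what gives the reported proportions uncertainty intervals; proportions
partition to 100% within every draw.  Observed-count aggregates (annual
totals, percent changes, quarter-of-year shares) are plain arithmetic on
reported counts and carry point values only — the package does not invent
an uncertainty model for observed totals.  Rounding to one decimal
(half-even) happens only at report emission.

Modelled prevalence can exceed 1 under a count model; such cells are
reported as-is with a warning, and draws are clipped to [0, 1] only where a
severity class must be assigned.

## Numerical notes

* NB log-pmf written via `log1p(r mu)/r` so the Poisson limit is accurate
  to ~1e-5 down to `r = 1e-8`; NB simulation via the gamma-Poisson mixture
  for the same reason.
* ICAR draws by eigen-decomposition of the dense Laplacian: exact, O(n^3),
  fine to a few hundred areas.
* Queen contiguity from polygons uses an STR-tree intersects query, so
  shared corners count as adjacency.
* Degenerate inputs: empty polygon sets, self-edges, out-of-range indices,
  non-positive denominators on observed cells, oversized holdouts and
  single-chain R-hat requests all raise informative `ValueError`s.
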