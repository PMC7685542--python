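"""WHO severity classification and posterior report tables.

The WHO grades anaemia prevalence as a public-health problem:
below 5% normal, 5-19.9% mild, 20-39.9% moderate, and 40% or above severe.
Classification is applied *per posterior draw* to each area's pooled
prevalence and the class proportions are then summarised over draws
(median and 2.5/97.5 percentiles), so the reported proportions carry
uncertainty intervals.  Observed-count aggregates (annual totals, percent
changes, quarterly shares) are plain arithmetic on the reported counts.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .mcmc import PosteriorChains
from .model import CountPanel, ExpectedCounts


class SeverityClass(enum.IntEnum):
    """Ordered public-health severity grades for anaemia prevalence."""

    NORMAL = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return {
            SeverityClass.NORMAL: "Normal",
            SeverityClass.MILD: "Mild",
            SeverityClass.MODERATE: "Moderate",
            SeverityClass.SEVERE: "Severe",
        }[self]


_THRESHOLDS = (0.05, 0.20, 0.40)


def classify_prevalence(p: float) -> SeverityClass:
    """Map a prevalence proportion to its WHO severity class.

    p < 0.05 normal; 0.05 <= p < 0.20 mild; 0.20 <= p < 0.40 moderate;
    p >= 0.40 severe.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {p}")
    if p < _THRESHOLDS[0]:
        return SeverityClass.NORMAL
    if p < _THRESHOLDS[1]:
        return SeverityClass.MILD
    if p < _THRESHOLDS[2]:
        return SeverityClass.MODERATE
    return SeverityClass.SEVERE


def _round1(x):
    """One-decimal rounding (round-half-even), applied only at emission."""
    return np.round(np.asarray(x, dtype=float), 1)


# ---------------------------------------------------------------------------
# observed-count arithmetic
# ---------------------------------------------------------------------------


def percent_change(base: float, new: float) -> float:
    """100 * (new - base) / base, reported to one decimal."""
    if base <= 0:
        raise ValueError("baseline count must be positive")
    return float(_round1(100.0 * (new - base) / base))


def quarterly_shares(totals) -> np.ndarray:
    """Per-quarter percentage shares of the total, to one decimal."""
    totals = np.asarray(totals, dtype=float)
    if np.any(totals < 0):
        raise ValueError("quarterly totals must be non-negative")
    s = totals.sum()
    if s <= 0:
        raise ValueError("at least one quarterly total must be positive")
    return _round1(100.0 * totals / s)


def observed_annual_totals(panel: CountPanel) -> dict[int, float]:
    """Plain sums of reported cases per calendar year (observed cells)."""
    obs = panel.observed_mask
    out = {}
    for year in panel.years:
        ts = panel.time_indices_for_year(year)
        sub = panel.cases[:, ts]
        out[year] = float(np.nansum(np.where(obs[:, ts], sub, 0.0)))
    return out


def observed_quarter_totals(panel: CountPanel) -> np.ndarray:
    """Reported cases summed by quarter-of-year (length 4)."""
    obs = panel.observed_mask
    out = np.zeros(4)
    for t, (_, q) in enumerate(panel.quarter_calendar):
        col = np.where(obs[:, t], panel.cases[:, t], 0.0)
        out[q - 1] += float(col.sum())
    return out


# ---------------------------------------------------------------------------
# posterior prevalence machinery
# ---------------------------------------------------------------------------


def _area_prevalence_draws(
    chains: PosteriorChains,
    panel: CountPanel,
    E: ExpectedCounts,
    time_idx: np.ndarray,
) -> np.ndarray:
    """Per-draw pooled prevalence for every area over the given quarters.

    Pooled, not quarter-averaged: sum_t E pi / sum_t N over cells with a
    positive denominator, so quarters are weighted by client volume.
    Shape (n_draws_total, n_areas); NaN for areas with no usable cell.
    """
    pi = chains.risk_draws()[:, :, time_idx]  # (S, I, Ty)
    Esub = E.E[:, time_idx]
    Nsub = panel.denominators[:, time_idx]
    ok = np.isfinite(Esub) & np.isfinite(Nsub) & (Nsub > 0)
    num = np.sum(np.where(ok, Esub, 0.0)[None] * np.where(ok[None], pi, 0.0), axis=2)
    den = np.sum(np.where(ok, Nsub, 0.0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = num / den[None, :]
    prev[:, den == 0] = np.nan
    return prev


def severity_class_fractions(
    chains: PosteriorChains,
    panel: CountPanel,
    E: ExpectedCounts,
    year: Optional[int] = None,
    area_subset: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-draw fraction of areas in each severity class, shape (S, 4).

    Prevalence draws above 1 are clipped to 1 for classification (the
    grading scale is defined on proportions).
    """
    time_idx = (
        panel.time_indices_for_year(year)
        if year is not None
        else np.arange(panel.n_times)
    )
    prev = _area_prevalence_draws(chains, panel, E, time_idx)
    if area_subset is not None:
        prev = prev[:, area_subset]
    valid = np.isfinite(prev).all(axis=0)
    prev = np.clip(prev[:, valid], 0.0, 1.0)
    n_areas = prev.shape[1]
    if n_areas == 0:
        raise ValueError("no areas with usable denominators for this slice")
    edges = np.array([-np.inf, *_THRESHOLDS, np.inf])
    cls = np.digitize(prev, edges[1:-1], right=False)  # 0..3
    fracs = np.stack(
        [(cls == k).sum(axis=1) / n_areas for k in range(4)], axis=1
    )
    return fracs


def severity_proportions(
    chains: PosteriorChains,
    panel: CountPanel,
    E: ExpectedCounts,
    year: Optional[int] = None,
    area_subset: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Class proportions (percent) with 95% uncertainty intervals."""
    fracs = 100.0 * severity_class_fractions(
        chains, panel, E, year=year, area_subset=area_subset
    )
    rows = []
    for k in range(4):
        rows.append(
            {
                "class": SeverityClass(k).label,
                "median": float(_round1(np.median(fracs[:, k]))),
                "q2.5": float(_round1(np.quantile(fracs[:, k], 0.025))),
                "q97.5": float(_round1(np.quantile(fracs[:, k], 0.975))),
            }
        )
    return pd.DataFrame(rows).set_index("class")


def stratify_by_zone(
    chains: PosteriorChains,
    panel: CountPanel,
    E: ExpectedCounts,
) -> pd.DataFrame:
    """Severity proportions within each endemicity zone, full period."""
    if panel.zone is None:
        raise ValueError("panel has no zone labels; stratification impossible")
    blank = [a for a, z in zip(panel.area_ids, panel.zone) if not z]
    if blank:
        raise ValueError(f"areas lacking a zone label: {blank}")
    frames = []
    for zone in sorted(set(panel.zone)):
        subset = np.array([z == zone for z in panel.zone])
        df = severity_proportions(chains, panel, E, area_subset=subset)
        df = df.assign(zone=zone).set_index("zone", append=True).swaplevel()
        frames.append(df)
    return pd.concat(frames)


def annual_case_totals(
    chains: PosteriorChains, panel: CountPanel, E: ExpectedCounts
) -> pd.DataFrame:
    """Observed and model-estimated case totals per year with 95% UIs."""
    pi = chains.risk_draws()
    obs = panel.observed_mask
    observed_totals = observed_annual_totals(panel)
    rows = []
    for year in panel.years:
        ts = panel.time_indices_for_year(year)
        ok = obs[:, ts] & np.isfinite(E.E[:, ts])
        cell_mu = np.where(ok[None], E.E[:, ts][None] * pi[:, :, ts], 0.0)
        totals = cell_mu.sum(axis=(1, 2))
        rows.append(
            {
                "year": year,
                "observed": observed_totals[year],
                "estimated_median": float(np.median(totals)),
                "estimated_q2.5": float(np.quantile(totals, 0.025)),
                "estimated_q97.5": float(np.quantile(totals, 0.975)),
            }
        )
    return pd.DataFrame(rows).set_index("year")


# ---------------------------------------------------------------------------
# prevalence summaries
# ---------------------------------------------------------------------------


@dataclass
class PrevalenceSummary:
    """Posterior prevalence summaries per cell and per area-year."""

    cell_table: pd.DataFrame
    area_year_table: pd.DataFrame

    def write_csv(self, cell_path, area_year_path) -> None:
        self.cell_table.to_csv(cell_path, index=False, float_format="%.6f")
        self.area_year_table.to_csv(
            area_year_path, index=False, float_format="%.6f"
        )

    @classmethod
    def read_csv(cls, cell_path, area_year_path) -> "PrevalenceSummary":
        return cls(
            cell_table=pd.read_csv(cell_path),
            area_year_table=pd.read_csv(area_year_path),
        )


def prevalence_summary(
    chains: PosteriorChains, panel: CountPanel, E: ExpectedCounts
) -> PrevalenceSummary:
    """Median and 95% UI of modelled prevalence per cell and per area-year.

    The area-year severity class is assigned from the median prevalence
    (the per-draw classification with uncertainty lives in
    :func:`severity_proportions`).
    """
    pi = chains.risk_draws()
    N = panel.denominators
    ok = np.isfinite(E.E) & np.isfinite(N) & (N > 0)
    cell_rows = []
    with np.errstate(invalid="ignore"):
        prev = np.where(ok[None], E.E[None] * pi / N[None], np.nan)
    if np.nanmax(prev) > 1.0:
        warnings.warn(
            "some modelled prevalence draws exceed 1; reported as-is in the "
            "cell table",
            stacklevel=2,
        )
    med = np.nanmedian(prev, axis=0)
    lo = np.nanquantile(prev, 0.025, axis=0)
    hi = np.nanquantile(prev, 0.975, axis=0)
    for i, aid in enumerate(panel.area_ids):
        for t, (year, quarter) in enumerate(panel.quarter_calendar):
            if not ok[i, t]:
                continue
            cell_rows.append(
                {
                    "area_id": aid,
                    "year": year,
                    "quarter": quarter,
                    "median": med[i, t],
                    "q2.5": lo[i, t],
                    "q97.5": hi[i, t],
                }
            )
    ay_rows = []
    for year in panel.years:
        ts = panel.time_indices_for_year(year)
        prev_ay = _area_prevalence_draws(chains, panel, E, ts)
        m = np.median(prev_ay, axis=0)
        l = np.quantile(prev_ay, 0.025, axis=0)
        h = np.quantile(prev_ay, 0.975, axis=0)
        for i, aid in enumerate(panel.area_ids):
            if not np.isfinite(m[i]):
                continue
            ay_rows.append(
                {
                    "area_id": aid,
                    "year": year,
                    "median": m[i],
                    "q2.5": l[i],
                    "q97.5": h[i],
                    "severity": classify_prevalence(
                        min(max(m[i], 0.0), 1.0)
                    ).label,
                }
            )
    return PrevalenceSummary(
        cell_table=pd.DataFrame(cell_rows),
        area_year_table=pd.DataFrame(ay_rows),
    )
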