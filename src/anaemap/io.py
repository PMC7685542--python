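"""File formats: panel CSV, adjacency edge lists / GAL files, draws CSV,
run manifests.

Area identifiers are opaque strings everywhere on disk; internal integer
indices follow the package-wide lexicographic ordering of area ids and
never leak into outputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .graphs import AdjacencyGraph, graph_from_edge_list
from .mcmc import McmcConfig, PosteriorChains, SCALAR_PARAMS
from .model import CountPanel, ModelState, PriorConfig

PANEL_COLUMNS = ("area_id", "year", "quarter", "cases", "new_clients")


# ---------------------------------------------------------------------------
# panel CSV
# ---------------------------------------------------------------------------


def read_panel_csv(
    path, column_map: Optional[dict[str, str]] = None
) -> CountPanel:
    """Read a long-format panel CSV (one row per area-quarter).

    ``column_map`` maps the file's headers onto the canonical schema,
    e.g. ``{"orgunit": "area_id"}``.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing panel columns {sorted(missing)}")
    if "zone" in df.columns:
        df["zone"] = df["zone"].fillna("")
    return CountPanel.from_dataframe(df)


def write_panel_csv(panel: CountPanel, path) -> None:
    panel.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# adjacency
# ---------------------------------------------------------------------------


def read_edge_list_csv(
    path, area_ids: Optional[Sequence[str]] = None
) -> tuple[AdjacencyGraph, tuple[str, ...]]:
    """Two-column CSV of neighbouring area-id pairs.

    If ``area_ids`` is given (e.g. from the panel), every id in the file
    must be among them and the graph is indexed in that order; otherwise
    the ordering is the lexicographic union of ids in the file.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns of area ids")
    a = df.iloc[:, 0].astype(str)
    b = df.iloc[:, 1].astype(str)
    if area_ids is None:
        ids = tuple(sorted(set(a) | set(b)))
    else:
        ids = tuple(area_ids)
        unknown = sorted((set(a) | set(b)) - set(ids))
        if unknown:
            raise ValueError(
                f"{path}: adjacency references areas absent from the panel: "
                f"{unknown}"
            )
    index = {aid: k for k, aid in enumerate(ids)}
    pairs = [(index[x], index[y]) for x, y in zip(a, b)]
    return graph_from_edge_list(pairs, len(ids)), ids


def write_edge_list_csv(
    graph: AdjacencyGraph, area_ids: Sequence[str], path
) -> None:
    ei, ej = graph.edge_arrays
    pd.DataFrame(
        {
            "area_id_a": [area_ids[i] for i in ei],
            "area_id_b": [area_ids[j] for j in ej],
        }
    ).to_csv(path, index=False)


def read_gal(
    path, area_ids: Optional[Sequence[str]] = None
) -> tuple[AdjacencyGraph, tuple[str, ...]]:
    """GAL neighbour file: a header count line, then alternating
    "id n_neighbours" / neighbour-id lines."""
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_by_line:
        raise ValueError(f"{path}: empty GAL file")
    header = tokens_by_line[0]
    # header is either "n" or the 4-token "0 n shapefile key" variant
    lines = tokens_by_line[1:]
    neighbours: dict[str, list[str]] = {}
    k = 0
    while k < len(lines):
        if len(lines[k]) != 2:
            raise ValueError(
                f"{path}: expected 'id count' pair, got {' '.join(lines[k])!r}"
            )
        aid, cnt = lines[k][0], int(lines[k][1])
        nbrs = lines[k + 1] if cnt > 0 else []
        if cnt > 0 and (k + 1 >= len(lines) or len(lines[k + 1]) != cnt):
            raise ValueError(f"{path}: area {aid} declares {cnt} neighbours")
        neighbours[aid] = list(nbrs)
        k += 2 if cnt > 0 else 1
    all_ids = set(neighbours)
    for nbrs in neighbours.values():
        all_ids.update(nbrs)
    ids = tuple(area_ids) if area_ids is not None else tuple(sorted(all_ids))
    unknown = sorted(all_ids - set(ids))
    if unknown:
        raise ValueError(f"{path}: unknown area ids {unknown}")
    index = {aid: i for i, aid in enumerate(ids)}
    pairs = [
        (index[aid], index[nbr])
        for aid, nbrs in neighbours.items()
        for nbr in nbrs
    ]
    return graph_from_edge_list(pairs, len(ids)), ids


# ---------------------------------------------------------------------------
# draws CSV
# ---------------------------------------------------------------------------


def write_draws_csv(chains: PosteriorChains, path) -> None:
    """Wide columnar draws file: chain, draw, scalars, then latent vectors
    with bracketed area/quarter labels in the headers."""
    frames = []
    ids = chains.area_ids
    cal = chains.quarter_calendar
    for c in range(chains.n_chains):
        cols = {"chain": np.full(chains.n_kept, c), "draw": np.arange(chains.n_kept)}
        for name in SCALAR_PARAMS:
            cols[name] = chains.draws[name][c]
        for i, aid in enumerate(ids):
            cols[f"u[{aid}]"] = chains.draws["u"][c, :, i]
        for i, aid in enumerate(ids):
            cols[f"v[{aid}]"] = chains.draws["v"][c, :, i]
        for t, (y, q) in enumerate(cal):
            cols[f"xi[{y}Q{q}]"] = chains.draws["xi"][c, :, t]
        for i, aid in enumerate(ids):
            for t, (y, q) in enumerate(cal):
                cols[f"nu[{aid},{y}Q{q}]"] = chains.draws["nu"][c, :, i, t]
        frames.append(pd.DataFrame(cols))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.8g"
    )


def read_draws_csv(path, panel: CountPanel) -> PosteriorChains:
    """Rebuild PosteriorChains from a draws CSV written for ``panel``."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: draws file is empty")
    chains_ids = sorted(df["chain"].unique())
    n_kept = int(df.groupby("chain").size().min())
    ids, cal = panel.area_ids, panel.quarter_calendar
    I, T = len(ids), len(cal)
    draws: dict[str, np.ndarray] = {
        name: np.empty((len(chains_ids), n_kept)) for name in SCALAR_PARAMS
    }
    draws["u"] = np.empty((len(chains_ids), n_kept, I))
    draws["v"] = np.empty((len(chains_ids), n_kept, I))
    draws["xi"] = np.empty((len(chains_ids), n_kept, T))
    draws["nu"] = np.empty((len(chains_ids), n_kept, I, T))
    for ci, c in enumerate(chains_ids):
        sub = df[df["chain"] == c].iloc[:n_kept]
        for name in SCALAR_PARAMS:
            draws[name][ci] = sub[name].to_numpy()
        for i, aid in enumerate(ids):
            draws["u"][ci, :, i] = sub[f"u[{aid}]"].to_numpy()
            draws["v"][ci, :, i] = sub[f"v[{aid}]"].to_numpy()
        for t, (y, q) in enumerate(cal):
            draws["xi"][ci, :, t] = sub[f"xi[{y}Q{q}]"].to_numpy()
        for i, aid in enumerate(ids):
            for t, (y, q) in enumerate(cal):
                draws["nu"][ci, :, i, t] = sub[f"nu[{aid},{y}Q{q}]"].to_numpy()
    cfg = McmcConfig(
        n_chains=len(chains_ids), n_iter=n_kept + 1, n_burnin=0, thin=1
    )
    return PosteriorChains(
        draws=draws,
        config=cfg,
        seed=-1,
        acceptance=[],
        area_ids=ids,
        quarter_calendar=cal,
    )


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------


def write_truth_json(truth: ModelState, path) -> None:
    doc = {
        "alpha": truth.alpha,
        "rho": truth.rho,
        "r": truth.r,
        "tau_u": truth.tau_u,
        "tau_v": truth.tau_v,
        "tau_xi": truth.tau_xi,
        "tau_nu": truth.tau_nu,
        "u": truth.u.tolist(),
        "v": truth.v.tolist(),
        "xi": truth.xi.tolist(),
        "nu": truth.nu.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record emitted next to every CLI output."""

    stage: str
    seed: int
    config_hash: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    metrics: dict[str, float] = field(default_factory=dict)
    version: str = __version__
    created: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    @classmethod
    def start(cls, stage: str, seed: int, config_obj, input_paths) -> "RunManifest":
        cfg_hash = hashlib.sha256(
            json.dumps(config_obj, sort_keys=True, default=str).encode()
        ).hexdigest()
        return cls(
            stage=stage,
            seed=seed,
            config_hash=cfg_hash,
            inputs={str(p): _sha256(p) for p in input_paths},
        )

    def write(self, path) -> None:
        doc = {
            "stage": self.stage,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "inputs": self.inputs,
            "outputs": self.outputs,
            "metrics": self.metrics,
            "version": self.version,
            "created": self.created,
        }
        Path(path).write_text(json.dumps(doc, indent=1))
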