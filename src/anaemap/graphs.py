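"""Areal adjacency graphs and the intrinsic CAR (ICAR) prior machinery.

The spatial prior used throughout the package is the intrinsic conditional
autoregressive (ICAR) Gaussian Markov random field: the joint kernel
penalises squared differences of the structured effect between contiguous
areas and is flat along per-component constants.  This module owns the
neighbourhood structure (binary, symmetric, no self-edges) and the two
densities the sampler needs — the joint kernel and the single-site full
conditional.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy import sparse


class IslandError(ValueError):
    """Raised when an ICAR full conditional is requested for a degree-0 area.

    Isolated areas carry no structured spatial information; the fitting code
    fixes their structured effect at zero and lets the unstructured BYM
    component absorb any area-level variation.
    """


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric binary contiguity graph over ``n_areas`` areal units.

    Edges are stored once per unordered pair ``(i, j)`` with ``i < j``.
    """

    n_areas: int
    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.n_areas <= 0:
            raise ValueError("n_areas must be a positive integer")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge ({i},{i}) is not allowed")
            if not (0 <= i < self.n_areas and 0 <= j < self.n_areas):
                raise ValueError(
                    f"edge ({i},{j}) references an area outside [0, {self.n_areas})"
                )

    # -- derived structure -------------------------------------------------

    @cached_property
    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two aligned integer arrays (each pair once)."""
        if not self.edges:
            empty = np.empty(0, dtype=np.intp)
            return empty, empty
        arr = np.asarray(self.edges, dtype=np.intp)
        return arr[:, 0], arr[:, 1]

    @cached_property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric 0/1 adjacency matrix (CSR)."""
        ei, ej = self.edge_arrays
        data = np.ones(2 * len(ei))
        rows = np.concatenate([ei, ej])
        cols = np.concatenate([ej, ei])
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_areas, self.n_areas)
        )

    @cached_property
    def degrees(self) -> np.ndarray:
        """Per-area neighbour count ``m_i``."""
        deg = np.zeros(self.n_areas, dtype=np.intp)
        ei, ej = self.edge_arrays
        np.add.at(deg, ei, 1)
        np.add.at(deg, ej, 1)
        return deg

    @cached_property
    def islands(self) -> np.ndarray:
        """Indices of degree-0 areas."""
        return np.flatnonzero(self.degrees == 0)

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[i] : self.adjacency.indptr[i + 1]
        ]

    @cached_property
    def _nx_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        g.add_edges_from(self.edges)
        return g

    @cached_property
    def component_labels(self) -> np.ndarray:
        """Deterministic connected-component labels.

        Components are labelled 0, 1, ... in order of their smallest member
        index, so the labelling does not depend on traversal order.
        """
        n_comp, labels = sparse.csgraph.connected_components(
            self.adjacency if self.edges else sparse.csr_matrix(
                (self.n_areas, self.n_areas)
            ),
            directed=False,
        )
        # relabel by smallest member index for determinism
        order = {}
        out = np.empty(self.n_areas, dtype=np.intp)
        for idx in range(self.n_areas):
            lab = labels[idx]
            if lab not in order:
                order[lab] = len(order)
            out[idx] = order[lab]
        return out

    @property
    def n_components(self) -> int:
        return int(self.component_labels.max()) + 1 if self.n_areas else 0

    @cached_property
    def icar_rank(self) -> int:
        """Rank of the ICAR precision: non-island areas minus their components."""
        non_island = self.n_areas - len(self.islands)
        comps = np.unique(self.component_labels[self.degrees > 0])
        return non_island - len(comps)

    @cached_property
    def coloring(self) -> np.ndarray:
        """Greedy proper colouring (deterministic); same-colour areas are
        conditionally independent under the ICAR prior, enabling vectorised
        single-site updates."""
        colors = nx.greedy_color(self._nx_graph, strategy="largest_first")
        return np.array([colors[i] for i in range(self.n_areas)], dtype=np.intp)


def graph_from_edge_list(
    pairs: Iterable[tuple[int, int]], n_areas: int
) -> AdjacencyGraph:
    """Build a graph from (possibly duplicated, possibly reversed) index pairs."""
    seen: set[tuple[int, int]] = set()
    for i, j in pairs:
        i, j = int(i), int(j)
        if i == j:
            raise ValueError(f"self-edge ({i},{i}) is not allowed")
        if not (0 <= i < n_areas and 0 <= j < n_areas):
            raise ValueError(f"edge ({i},{j}) out of range for {n_areas} areas")
        seen.add((min(i, j), max(i, j)))
    return AdjacencyGraph(n_areas=n_areas, edges=tuple(sorted(seen)))


def graph_from_polygons(polygons: Sequence) -> AdjacencyGraph:
    """Queen contiguity: areas whose polygons share at least one boundary
    point are neighbours.

    ``polygons`` is an ordered sequence of shapely geometries; the order
    defines the area indexing.
    """
    from shapely import STRtree

    polygons = list(polygons)
    if len(polygons) == 0:
        raise ValueError("polygon collection is empty")
    for k, geom in enumerate(polygons):
        if geom is None or geom.is_empty or not geom.is_valid:
            raise ValueError(f"invalid or empty geometry at position {k}")
    tree = STRtree(polygons)
    left, right = tree.query(polygons, predicate="intersects")
    pairs = {(int(i), int(j)) for i, j in zip(left, right) if i < j}
    return AdjacencyGraph(n_areas=len(polygons), edges=tuple(sorted(pairs)))


def graph_from_geojson(path) -> tuple[AdjacencyGraph, tuple[str, ...]]:
    """Queen-contiguity graph from a GeoJSON FeatureCollection.

    Features must carry an ``area_id`` property; areas are ordered
    lexicographically by that id (the package-wide indexing convention).
    Returns the graph and the ordered area ids.
    """
    from shapely.geometry import shape

    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", [])
    if not feats:
        raise ValueError(f"{path}: no features in GeoJSON FeatureCollection")
    records = []
    for k, feat in enumerate(feats):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise ValueError(f"{path}: feature {k} lacks an 'area_id' property")
        records.append((str(props["area_id"]), shape(feat["geometry"])))
    records.sort(key=lambda rec: rec[0])
    ids = tuple(r[0] for r in records)
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate area_id values")
    return graph_from_polygons([r[1] for r in records]), ids


def icar_pairwise_sum(u: np.ndarray, graph: AdjacencyGraph) -> float:
    """The ICAR quadratic form sum_{i~j} (u_i - u_j)^2, each pair once."""
    ei, ej = graph.edge_arrays
    diff = u[ei] - u[ej]
    return float(diff @ diff)


def icar_log_density(u: np.ndarray, tau: float, graph: AdjacencyGraph) -> float:
    """Log density of the ICAR prior, up to a constant not involving ``u``.

    Returns ``(n - c)/2 * log(tau) - tau/2 * sum_{i~j}(u_i - u_j)^2`` where
    the rank ``n - c`` counts non-island areas minus connected components —
    the rank of the (improper) ICAR precision matrix.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (graph.n_areas,):
        raise ValueError(
            f"u has length {u.shape}, expected ({graph.n_areas},)"
        )
    if tau <= 0:
        raise ValueError("tau must be positive")
    return 0.5 * graph.icar_rank * np.log(tau) - 0.5 * tau * icar_pairwise_sum(
        u, graph
    )


def icar_full_conditional(
    u: np.ndarray, i: int, tau: float, graph: AdjacencyGraph
) -> tuple[float, float]:
    """Gaussian full conditional of ``u_i`` under the ICAR prior.

    Returns ``(mean, precision)`` = (average of neighbours, tau * degree).
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (graph.n_areas,):
        raise ValueError(f"u has length {u.shape}, expected ({graph.n_areas},)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    nbrs = graph.neighbors(i)
    if len(nbrs) == 0:
        raise IslandError(
            f"area {i} has no neighbours; the island policy applies "
            "(structured effect fixed at 0)"
        )
    return float(u[nbrs].mean()), float(tau * len(nbrs))


def morans_i(x: np.ndarray, graph: AdjacencyGraph) -> float:
    """Moran's I spatial autocorrelation of ``x`` under binary weights."""
    x = np.asarray(x, dtype=float)
    if x.shape != (graph.n_areas,):
        raise ValueError("x must have one value per area")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0.0:
        raise ValueError("x is constant; Moran's I undefined")
    ei, ej = graph.edge_arrays
    num = 2.0 * float(xc[ei] @ xc[ej])  # both orientations of each pair
    w_sum = 2.0 * len(ei)
    return (graph.n_areas / w_sum) * (num / denom)
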