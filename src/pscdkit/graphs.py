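"""Density thresholding, conventional graph attributes and rewiring nulls.

The workflow follows the standard binary-connectome tradition: a
connectivity matrix is proportionally thresholded at a set of edge
densities (0.05, 0.10, 0.15, 0.20 by default), and on each binary graph
five attributes are computed -- two integration measures (characteristic
path length, global efficiency) and three segregation measures
(modularity, clustering coefficient, transitivity).  Each raw attribute is
normalized against a null distribution of degree-preserving randomly
rewired graphs (100 iterations by default).  Characteristic path length is
inverted during normalization (null mean / raw) so that for every
normalized attribute lower = worse function.

Thresholded resting-state graphs at low density are routinely
disconnected; path length therefore averages over reachable pairs only and
global efficiency scores unreachable pairs as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities
from networkx.algorithms.community import modularity as nx_modularity
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

__all__ = [
    "BinaryGraph",
    "Partition",
    "AttributeProfile",
    "ATTRIBUTES",
    "threshold_by_density",
    "characteristic_path_length",
    "global_efficiency",
    "clustering_coefficient",
    "transitivity",
    "modularity_louvain",
    "rewire_null",
    "attribute_profile",
]

#: attribute names in the conventional reporting order
ATTRIBUTES = (
    "inv_char_path_length",
    "global_efficiency",
    "modularity",
    "clustering_coefficient",
    "transitivity",
)


@dataclass
class BinaryGraph:
    """Undirected simple graph as a symmetric 0/1 adjacency matrix."""

    adjacency: np.ndarray
    node_labels: list[str]
    density: float = field(init=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        self.adjacency = a.astype(np.int8)
        if len(self.node_labels) != a.shape[0]:
            raise ValueError("node_labels length does not match adjacency")
        n = a.shape[0]
        self.density = float(a.sum()) / (n * (n - 1)) if n > 1 else 0.0

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_list(self) -> list[tuple[int, int]]:
        iu, ju = np.nonzero(np.triu(self.adjacency, 1))
        return list(zip(iu.tolist(), ju.tolist()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edge_list())
        return g


@dataclass
class Partition:
    """Community assignment plus the Newman-Girvan modularity it achieves."""

    assignment: dict[int, int]
    q_value: float


def threshold_by_density(c: ConnectivityMatrix, density: float) -> BinaryGraph:
    """Keep the ``floor(density * n(n-1)/2)`` strongest positive weights.

    Negative entries are never edge candidates.  Ties are broken by
    lexicographic (i, j) node-index order so thresholding is fully
    deterministic.  If fewer positive weights exist than requested, all of
    them are kept and a warning records the achieved density.
    """
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    n = c.n_nodes
    target = math.floor(density * n * (n - 1) / 2)
    iu, ju = np.triu_indices(n, 1)
    w = c.values[iu, ju]
    pos = w > 0
    iu, ju, w = iu[pos], ju[pos], w[pos]
    # stable sort on descending weight; original (i, j) order resolves ties
    order = np.argsort(-w, kind="stable")
    if order.size < target:
        warnings.warn(
            f"only {order.size} positive weights available for "
            f"{target} requested edges; achieved density will be lower"
        )
    keep = order[:target]
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[keep], ju[keep]] = 1
    a |= a.T
    return BinaryGraph(a, list(c.node_labels))


def _distance_matrix(g: BinaryGraph) -> np.ndarray:
    return shortest_path(g.adjacency, method="D", unweighted=True, directed=False)


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path length over reachable ordered pairs i != j.

    Unreachable pairs are excluded from the mean; an edgeless graph has no
    defined path length and raises.
    """
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if g.n_edges == 0:
        raise ValueError("characteristic path length undefined on an edgeless graph")
    d = _distance_matrix(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    finite = np.isfinite(d) & off
    return float(d[finite].mean())


def global_efficiency(g: BinaryGraph) -> float:
    """Mean of 1/d(i, j) over all ordered pairs i != j, with 1/inf = 0."""
    if g.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    d = _distance_matrix(g)
    off = ~np.eye(g.n_nodes, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean nodal clustering, C_i = 2 t_i / (k_i (k_i - 1)); C_i = 0 if k_i < 2."""
    if g.n_nodes < 1:
        raise ValueError("need at least 1 node")
    return float(nx.average_clustering(g.to_networkx()))


def transitivity(g: BinaryGraph) -> float:
    """3 x triangles / connected triples; undefined without any triple."""
    a = g.adjacency.astype(np.int64)
    k = a.sum(axis=1)
    triples = int((k * (k - 1) // 2).sum())
    if triples == 0:
        raise ValueError("transitivity undefined: graph has no connected triple")
    triangles = int(np.trace(a @ a @ a)) // 6
    return 3.0 * triangles / triples


def modularity_louvain(
    g: BinaryGraph, seed: int = 0, n_restarts: int = 10
) -> Partition:
    """Best-of-``n_restarts`` Louvain community detection (resolution 1).

    Node order is randomized per restart through the seed; the partition
    with the highest Newman-Girvan Q is returned.
    """
    if g.n_edges == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    gx = g.to_networkx()
    best_q, best_comms = -np.inf, None
    for r in range(n_restarts):
        comms = louvain_communities(gx, seed=seed * n_restarts + r, resolution=1.0)
        q = nx_modularity(gx, comms, resolution=1.0)
        if q > best_q:
            best_q, best_comms = q, comms
    assignment = {node: ci for ci, comm in enumerate(best_comms) for node in comm}
    return Partition(assignment, float(best_q))


def rewire_null(
    g: BinaryGraph,
    n_iter: int = 100,
    swaps_per_edge: int = 10,
    seed: int = 0,
    attempt_factor: int = 40,
) -> list[BinaryGraph]:
    """Degree-preserving (Maslov-Sneppen) null ensemble.

    Each null graph is built from the input by double-edge swaps: pick two
    edges (a, b), (c, d), replace with (a, d), (c, b) when neither
    self-loops nor duplicates an existing edge.  The target is
    ``swaps_per_edge`` accepted swaps per edge with an attempt budget of
    ``attempt_factor`` times the target; graphs admitting no valid swap
    (e.g. stars) are returned as copies with a warning that the null is
    degenerate.
    """
    if g.n_edges < 2:
        raise ValueError("rewiring requires at least 2 edges")
    nulls: list[BinaryGraph] = []
    degenerate = 0
    for it in range(n_iter):
        rng = np.random.default_rng([seed, it])
        a = g.adjacency.copy()
        edges = g.edge_list()
        target = swaps_per_edge * len(edges)
        budget = attempt_factor * target
        accepted = 0
        while accepted < target and budget > 0:
            budget -= 1
            e1, e2 = rng.integers(0, len(edges), size=2)
            if e1 == e2:
                continue
            u, v = edges[e1]
            x, y = edges[e2]
            if rng.integers(2):
                x, y = y, x
            # proposed: (u, x), (v, y)
            if len({u, v, x, y}) < 4:
                continue
            if a[u, x] or a[v, y]:
                continue
            a[u, v] = a[v, u] = 0
            a[x, y] = a[y, x] = 0
            a[u, x] = a[x, u] = 1
            a[v, y] = a[y, v] = 1
            edges[e1] = (min(u, x), max(u, x))
            edges[e2] = (min(v, y), max(v, y))
            accepted += 1
        if accepted == 0:
            degenerate += 1
        nulls.append(BinaryGraph(a, list(g.node_labels)))
    if degenerate:
        warnings.warn(
            f"null ensemble degenerate: {degenerate}/{n_iter} graphs admitted "
            "no valid double-edge swap and were returned as copies"
        )
    return nulls


def _raw_attributes(g: BinaryGraph, seed: int, n_restarts: int) -> dict[str, float]:
    """The five attributes; undefined values are recorded as NaN."""
    out: dict[str, float] = {}
    try:
        out["char_path_length"] = characteristic_path_length(g)
    except ValueError:
        out["char_path_length"] = math.nan
    out["global_efficiency"] = global_efficiency(g)
    try:
        out["modularity"] = modularity_louvain(g, seed=seed, n_restarts=n_restarts).q_value
    except ValueError:
        out["modularity"] = math.nan
    out["clustering_coefficient"] = clustering_coefficient(g)
    try:
        out["transitivity"] = transitivity(g)
    except ValueError:
        out["transitivity"] = math.nan
    return out


@dataclass
class AttributeProfile:
    """Raw / null mean / null sd / normalized attributes per density.

    ``values[density][attribute]`` is a dict with keys ``raw``,
    ``null_mean``, ``null_sd`` and ``normalized``.  Normalization is
    raw / null_mean for every attribute except the inverted characteristic
    path length, where it is null_mean / raw so that larger = better for
    all five.  Undefined quantities are NaN, never silently zeroed.
    """

    values: dict[float, dict[str, dict[str, float]]]
    densities: list[float]
    n_null: int

    def normalized(self, density: float, attribute: str) -> float:
        return self.values[density][attribute]["normalized"]

    def normalized_mean(self, attribute: str) -> float:
        """Attribute averaged across all configured densities."""
        return float(
            np.mean([self.values[d][attribute]["normalized"] for d in self.densities])
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.densities:
            for attr, vals in self.values[d].items():
                rows.append({"density": d, "attribute": attr, **vals})
        return pd.DataFrame(rows)


def attribute_profile(
    c: ConnectivityMatrix,
    densities: tuple[float, ...] = (0.05, 0.10, 0.15, 0.20),
    n_null: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
    n_restarts: int = 10,
) -> AttributeProfile:
    """Threshold, measure and null-normalize at each density."""
    if not densities:
        raise ValueError("densities must be nonempty")
    values: dict[float, dict[str, dict[str, float]]] = {}
    for di, density in enumerate(densities):
        try:
            g = threshold_by_density(c, density)
            raw = _raw_attributes(g, seed=seed + di, n_restarts=n_restarts)
            nulls = rewire_null(
                g, n_iter=n_null, swaps_per_edge=swaps_per_edge, seed=seed * 1009 + di
            )
            null_raw = [
                _raw_attributes(ng, seed=seed + di, n_restarts=n_restarts)
                for ng in nulls
            ]
        except ValueError as err:
            raise ValueError(f"density {density}: {err}") from err
        entry: dict[str, dict[str, float]] = {}
        for attr in ATTRIBUTES:
            key = "char_path_length" if attr == "inv_char_path_length" else attr
            r = raw[key]
            nv = np.array([x[key] for x in null_raw])
            n_mean = float(np.nanmean(nv)) if np.isfinite(nv).any() else math.nan
            n_sd = float(np.nanstd(nv, ddof=1)) if np.isfinite(nv).sum() > 1 else math.nan
            if attr == "inv_char_path_length":
                norm = n_mean / r if math.isfinite(r) and math.isfinite(n_mean) and r > 0 else math.nan
            else:
                norm = r / n_mean if math.isfinite(r) and math.isfinite(n_mean) and n_mean != 0 else math.nan
            entry[attr] = {
                "raw": float(r),
                "null_mean": n_mean,
                "null_sd": n_sd,
                "normalized": float(norm),
            }
        values[density] = entry
    return AttributeProfile(values, list(densities), n_null)
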