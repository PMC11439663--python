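"""Independent brute-force oracles used to validate the graph metrics.

Everything here is deliberately naive (queue-based BFS, per-node triangle
enumeration, exhaustive partition search, hypergeometric tail sums) and
shares no code with the implementation it checks.
"""

from __future__ import annotations

from collections import deque
from itertools import combinations
from math import comb

import numpy as np


def bfs_distances(adj: np.ndarray, source: int) -> list[float]:
    n = adj.shape[0]
    dist = [float("inf")] * n
    dist[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v in range(n):
            if adj[u, v] and dist[v] == float("inf"):
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def oracle_cpl(adj: np.ndarray) -> float:
    """Mean BFS distance over reachable ordered pairs i != j."""
    n = adj.shape[0]
    total, count = 0.0, 0
    for i in range(n):
        for j, d in enumerate(bfs_distances(adj, i)):
            if i != j and d != float("inf"):
                total += d
                count += 1
    if count == 0:
        raise ValueError("no reachable pair")
    return total / count


def oracle_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        for j, d in enumerate(bfs_distances(adj, i)):
            if i != j and d != float("inf"):
                total += 1.0 / d
    return total / (n * (n - 1))


def oracle_clustering(adj: np.ndarray) -> float:
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        t = sum(1 for a, b in combinations(nbrs, 2) if adj[a, b])
        cs.append(2.0 * t / (k * (k - 1)))
    return float(np.mean(cs))


def oracle_transitivity(adj: np.ndarray) -> float:
    n = adj.shape[0]
    triangles = sum(
        1
        for a, b, c in combinations(range(n), 3)
        if adj[a, b] and adj[b, c] and adj[a, c]
    )
    triples = sum(comb(int(adj[i].sum()), 2) for i in range(n))
    if triples == 0:
        raise ValueError("no connected triple")
    return 3.0 * triangles / triples


def q_of_partition(adj: np.ndarray, labels) -> float:
    """Newman-Girvan modularity of a given node labeling."""
    labels = np.asarray(labels)
    m2 = adj.sum()  # 2|E|
    if m2 == 0:
        raise ValueError("edgeless graph")
    k = adj.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(((adj - np.outer(k, k) / m2) * same).sum() / m2)


def _set_partitions(items: list[int]):
    """All partitions of a list (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def oracle_best_modularity(adj: np.ndarray) -> float:
    """Exhaustive maximum modularity over every partition (small n only)."""
    n = adj.shape[0]
    best = -np.inf
    for part in _set_partitions(list(range(n))):
        labels = np.empty(n, dtype=int)
        for ci, block in enumerate(part):
            labels[block] = ci
        best = max(best, q_of_partition(adj, labels))
    return best


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric tail enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def spearman_oracle(x, y) -> float:
    """1 - 6 sum(d^2) / (n (n^2 - 1)); valid only without ties."""
    x, y = np.asarray(x), np.asarray(y)
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    n = len(x)
    return 1.0 - 6.0 * float(((rx - ry) ** 2).sum()) / (n * (n * n - 1))


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
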