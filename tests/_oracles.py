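"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit BFS, subset enumeration,
per-sample loops) and shares no code with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import factorial

import numpy as np


# -- graphs -----------------------------------------------------------------


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by explicit BFS; inf if unreachable."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in np.flatnonzero(adj[u]):
                    if v not in seen:
                        seen.add(v)
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def components(adj: np.ndarray) -> list[list[int]]:
    dist = bfs_distances(adj)
    remaining = set(range(adj.shape[0]))
    out = []
    while remaining:
        s = min(remaining)
        comp = sorted(v for v in remaining if np.isfinite(dist[s, v]))
        out.append(comp)
        remaining -= set(comp)
    return out


def largest_component(adj: np.ndarray) -> list[int]:
    comps = components(adj)
    best = max(len(c) for c in comps)
    return next(c for c in comps if len(c) == best)


def apl_largest_component(adj: np.ndarray) -> float:
    nodes = largest_component(adj)
    if len(nodes) < 2:
        return 0.0
    dist = bfs_distances(adj[np.ix_(nodes, nodes)])
    vals = [dist[i, j] for i in range(len(nodes)) for j in range(len(nodes)) if i != j]
    return float(np.mean(vals))


def diameter_largest_component(adj: np.ndarray) -> float:
    nodes = largest_component(adj)
    if len(nodes) < 2:
        return 0.0
    dist = bfs_distances(adj[np.ix_(nodes, nodes)])
    return float(dist[np.isfinite(dist)].max())


def mean_eccentricity_largest_component(adj: np.ndarray) -> float:
    nodes = largest_component(adj)
    if len(nodes) < 2:
        return 0.0
    dist = bfs_distances(adj[np.ix_(nodes, nodes)])
    return float(np.mean(dist.max(axis=1)))


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    dist = bfs_distances(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def transitivity(adj: np.ndarray) -> float:
    n = adj.shape[0]
    triangles = 0
    triples = 0
    for i, j, k in combinations(range(n), 3):
        edges = adj[i, j] + adj[j, k] + adj[i, k]
        if edges == 3:
            triangles += 1
        # a connected triple is a path of length 2 centred at some node
    for c in range(n):
        neigh = np.flatnonzero(adj[c])
        triples += len(neigh) * (len(neigh) - 1) // 2
    return 3.0 * triangles / triples if triples else 0.0


def mean_closeness(adj: np.ndarray) -> float:
    """Mean of per-node closeness (reachable-1)/sum(d), isolated -> 0."""
    n = adj.shape[0]
    dist = bfs_distances(adj)
    vals = []
    for i in range(n):
        reach = [dist[i, j] for j in range(n) if j != i and np.isfinite(dist[i, j])]
        vals.append((len(reach)) / sum(reach) if reach else 0.0)
    return float(np.mean(vals))


def max_normalized_eigenvector(adj: np.ndarray, n_iter: int = 10000) -> np.ndarray:
    """Perron vector by power iteration, scaled to max 1 (connected graphs)."""
    n = adj.shape[0]
    v = np.ones(n)
    for _ in range(n_iter):
        nv = adj @ v
        if nv.max() == 0:
            return np.zeros(n)
        nv = nv / np.linalg.norm(nv)
        if np.allclose(nv, v, atol=1e-14):
            v = nv
            break
        v = nv
    return v / v.max()


# -- shapley ----------------------------------------------------------------


def shapley_bruteforce(model_fn, x: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Shapley values by explicit subset enumeration, one subset at a time."""
    d = x.size
    phi = np.zeros(d)
    features = list(range(d))

    def value(subset: tuple) -> float:
        scores = []
        for b in background:
            z = b.copy()
            for f in subset:
                z[f] = x[f]
            scores.append(float(model_fn(z[None, :])[0]))
        return float(np.mean(scores))

    for j in features:
        others = [f for f in features if f != j]
        for size in range(d):
            for subset in combinations(others, size):
                w = factorial(size) * factorial(d - size - 1) / factorial(d)
                phi[j] += w * (value(subset + (j,)) - value(subset))
    return phi


# -- bootstrap --------------------------------------------------------------


def bootstrap_lower_ci(values, n_boot=1000, alpha=0.05, seed=0):
    """Percentile-bootstrap lower bound of the mean, coded independently."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    means = []
    for _ in range(n_boot):
        sample = values[rng.integers(0, values.size, size=values.size)]
        means.append(sample.mean())
    return float(np.percentile(np.asarray(means), 100 * alpha / 2))


# -- binary correlation -----------------------------------------------------


def phi_coefficient(x: np.ndarray, y: np.ndarray) -> float:
    """Phi coefficient from the 2x2 contingency table of two binary vectors."""
    n11 = int(np.sum((x == 1) & (y == 1)))
    n10 = int(np.sum((x == 1) & (y == 0)))
    n01 = int(np.sum((x == 0) & (y == 1)))
    n00 = int(np.sum((x == 0) & (y == 0)))
    denom = np.sqrt(
        float(n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    )
    if denom == 0:
        return 0.0
    return (n11 * n00 - n10 * n01) / denom


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Hand-rolled Pearson correlation."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom) if denom > 0 else 0.0
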