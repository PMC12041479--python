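"""Complex-network measures and community features of binary graphs.

From each thresholded connectivity graph 25 scalar features are computed:

* 17 classical measures: assortativity, mean average-neighbor degree (knn),
  average shortest path length (apl), mean normalized betweenness (bc), mean
  closeness (cc), complexity, density, diameter, mean eccentricity, mean
  eigenvector centrality (ec), global efficiency, degree-distribution entropy
  (ed), mean hub score, degeneracy (k_core), mean degree, second moment of the
  degree distribution (smd), and transitivity;
* 8 community features (afc, aic, alc, alpc, aebc, aspc, amc, asc): the
  average path length within the largest community found by one of eight
  community-detection algorithms.

Conventions for degenerate graphs keep every window scoreable: distance-based
measures are evaluated on the largest connected component; global efficiency
uses 1/inf = 0 over all ordered pairs; an edgeless graph scores 0 for
apl/diameter/eccentricity; assortativity of a regular graph (undefined
Pearson) is 0.

``complexity`` is the degree-distribution heterogeneity ratio
``<k^2>/<k>`` (second moment over mean degree), consistent with ``smd``
being listed separately; the reduction of per-node measures to a scalar is
the arithmetic mean.  Both choices are overridable where ambiguity exists in
the upstream literature.
"""

from __future__ import annotations

import logging
import random as _pyrandom

import igraph as ig
import numpy as np

logger = logging.getLogger(__name__)


def _seed_igraph(seed: int) -> None:
    """Seed the RNG igraph draws from (ARPACK start vectors, stochastic
    community methods).  python-igraph uses Python's global random module."""
    _pyrandom.seed(seed)

#: canonical feature order of the 17 scalar measures
SCALAR_MEASURES = (
    "assortativity",
    "knn",
    "apl",
    "bc",
    "cc",
    "complexity",
    "density",
    "diameter",
    "eccentricity",
    "ec",
    "efficiency",
    "ed",
    "hub_score",
    "k_core",
    "mean_degree",
    "smd",
    "transitivity",
)

#: community feature name -> community-detection algorithm
COMMUNITY_METHODS = {
    "afc": "fastgreedy",
    "aic": "infomap",
    "alc": "leading_eigenvector",
    "alpc": "label_propagation",
    "aebc": "edge_betweenness",
    "aspc": "spinglass",
    "amc": "multilevel",
    "asc": "spanning_tree",
}

#: all 25 graph features in canonical order
FEATURE_NAMES = SCALAR_MEASURES + tuple(COMMUNITY_METHODS)

_STOCHASTIC_METHODS = {"infomap", "label_propagation", "spinglass"}


def _as_graph(adjacency: np.ndarray) -> ig.Graph:
    A = np.asarray(adjacency)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("adjacency must be square")
    if n < 2:
        raise ValueError("graph must have at least 2 nodes")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must have zero diagonal")
    edges = np.argwhere(np.triu(A, 1) > 0)
    g = ig.Graph(n=n, edges=[(int(i), int(j)) for i, j in edges], directed=False)
    return g


def _principal_vector(M: np.ndarray, tol: float = 1e-14, max_iter: int = 20000) -> np.ndarray:
    """Dominant eigenvector of a symmetric non-negative-spectrum matrix by
    power iteration from the all-ones vector, scaled to max 1.

    The canonical ones start makes the result deterministic and
    permutation-equivariant even when the dominant eigenvalue is degenerate
    (the iteration converges to the projection of the ones vector onto the
    dominant eigenspace)."""
    v = np.ones(M.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        w = M @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return np.zeros(M.shape[0])
        w /= norm
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    vmax = v.max()
    return v / vmax if vmax > 0 else v


def scalar_measures(adjacency: np.ndarray, reduction: str = "mean") -> dict[str, float]:
    """The 17 scalar complex-network measures of a simple undirected graph."""
    g = _as_graph(adjacency)
    n = g.vcount()
    reduce_ = np.median if reduction == "median" else np.mean
    deg = np.asarray(g.degree(), dtype=float)
    out: dict[str, float] = {}
    out["mean_degree"] = float(deg.mean())
    out["smd"] = float((deg**2).mean())
    out["complexity"] = out["smd"] / out["mean_degree"] if out["mean_degree"] > 0 else 0.0
    _, counts = np.unique(deg, return_counts=True)
    p = counts / n
    out["ed"] = float(-(p * np.log2(p)).sum())
    m = g.ecount()
    out["density"] = 2.0 * m / (n * (n - 1))
    out["transitivity"] = float(g.transitivity_undirected(mode="zero"))

    if m == 0:
        logger.debug("edgeless graph: distance measures set to 0 by convention")
        for key in ("apl", "diameter", "eccentricity", "efficiency", "bc", "cc",
                    "ec", "hub_score", "knn", "assortativity"):
            out[key] = 0.0
        out["k_core"] = 0.0
        return out

    comps = g.connected_components()
    giant = comps.giant()
    out["apl"] = float(giant.average_path_length(directed=False))
    out["diameter"] = float(giant.diameter())
    out["eccentricity"] = float(reduce_(giant.eccentricity()))

    dist = np.asarray(g.distances())
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    out["efficiency"] = float(inv.sum() / (n * (n - 1)))

    bc = np.asarray(g.betweenness(), dtype=float)
    out["bc"] = float(reduce_(bc / ((n - 1) * (n - 2) / 2.0))) if n > 2 else 0.0
    closeness = np.asarray(g.closeness(mode="all", normalized=True), dtype=float)
    out["cc"] = float(reduce_(np.nan_to_num(closeness, nan=0.0)))
    A = np.asarray(adjacency, dtype=float)
    out["ec"] = float(reduce_(_principal_vector(A + np.eye(n))))
    out["hub_score"] = float(reduce_(_principal_vector(A @ A + np.eye(n))))
    knn_per_node = np.asarray(g.knn()[0], dtype=float)
    finite = np.isfinite(knn_per_node)
    out["knn"] = float(reduce_(knn_per_node[finite])) if finite.any() else 0.0
    out["k_core"] = float(max(g.coreness()))
    assort = g.assortativity_degree(directed=False)
    out["assortativity"] = 0.0 if assort is None or not np.isfinite(assort) else float(assort)
    return out


def _spanning_tree_communities(g: ig.Graph) -> list[int]:
    """Spanning-forest splitting: iteratively remove the forest edge with the
    highest edge betweenness and keep the split sequence maximizing modularity
    of the original graph.  Deterministic stand-in for tree-based community
    detection."""
    forest = g.spanning_tree()
    best = g.connected_components().membership
    best_q = g.modularity(best)
    work = forest.copy()
    while work.ecount() > 0:
        eb = work.edge_betweenness()
        work.delete_edges(int(np.argmax(eb)))
        mem = work.connected_components().membership
        q = g.modularity(mem)
        if q > best_q:
            best, best_q = mem, q
    return list(best)


def detect_communities(
    adjacency: np.ndarray, method: str, seed: int = 0
) -> np.ndarray:
    """Partition the nodes with a named community-detection algorithm.

    Stochastic methods (infomap, label_propagation, spinglass) are made
    deterministic by seeding igraph's RNG.  Spinglass requires a connected
    graph and is run on the largest component; remaining nodes become
    singleton communities.  An edgeless graph yields all singletons.
    """
    methods = set(COMMUNITY_METHODS.values())
    if method not in methods:
        raise ValueError(f"unknown community method {method!r}; expected {sorted(methods)}")
    g = _as_graph(adjacency)
    n = g.vcount()
    if g.ecount() == 0:
        return np.arange(n)
    # all methods: ARPACK-based ones draw random start vectors too
    _seed_igraph(seed)
    if method == "fastgreedy":
        membership = g.community_fastgreedy().as_clustering().membership
    elif method == "infomap":
        membership = g.community_infomap().membership
    elif method == "leading_eigenvector":
        # ARPACK occasionally rejects a random start vector; retry on a
        # deterministic seed ladder
        for attempt in range(10):
            _seed_igraph(seed + attempt)
            try:
                membership = g.community_leading_eigenvector().membership
                break
            except ig.InternalError:
                if attempt == 9:
                    raise
    elif method == "label_propagation":
        membership = g.community_label_propagation().membership
    elif method == "edge_betweenness":
        membership = g.community_edge_betweenness(directed=False).as_clustering().membership
    elif method == "multilevel":
        membership = g.community_multilevel().membership
    elif method == "spinglass":
        comps = g.connected_components()
        sizes = comps.sizes()
        giant_cid = int(np.argmax(sizes))
        vertices = [v for v, c in enumerate(comps.membership) if c == giant_cid]
        sub = g.induced_subgraph(vertices)
        membership = np.full(n, -1, dtype=int)
        if sub.ecount() > 0:
            sub_mem = sub.community_spinglass().membership
            for v, c in zip(vertices, sub_mem):
                membership[v] = c
        next_id = int(membership.max()) + 1
        for v in range(n):
            if membership[v] < 0:
                membership[v] = next_id
                next_id += 1
        return membership
    else:  # spanning_tree
        membership = _spanning_tree_communities(g)
    return np.asarray(membership, dtype=int)


def community_apl(adjacency: np.ndarray, method: str, seed: int = 0) -> float:
    """Average path length within the largest detected community.

    Ties on community size are broken toward the community containing the
    smallest node id.  The APL is taken over the largest connected component
    of the induced subgraph; a singleton or edgeless community scores 0.
    """
    membership = detect_communities(adjacency, method, seed=seed)
    ids, counts = np.unique(membership, return_counts=True)
    biggest = ids[counts == counts.max()]
    # smallest minimum node id among tied communities
    winner = min(biggest, key=lambda c: int(np.flatnonzero(membership == c)[0]))
    nodes = np.flatnonzero(membership == winner)
    if nodes.size < 2:
        return 0.0
    sub = np.asarray(adjacency)[np.ix_(nodes, nodes)]
    g = _as_graph(sub)
    if g.ecount() == 0:
        return 0.0
    return float(g.connected_components().giant().average_path_length(directed=False))


def graph_features(
    adjacency: np.ndarray, seed: int = 0, reduction: str = "mean"
) -> dict[str, float]:
    """All 25 graph features (17 scalar measures + 8 community APLs)."""
    out = scalar_measures(adjacency, reduction=reduction)
    for feature, method in COMMUNITY_METHODS.items():
        out[feature] = community_apl(adjacency, method, seed=seed)
    return out
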