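"""Functional connectivity: pairwise correlation of binned spike trains.

The correlation matrix over the binary occupancy rows is thresholded at 0.5
(signed value, not absolute) into an undirected, unweighted graph whose nodes
are the active electrodes.  Zero-variance (silent) rows correlate 0 with every
partner by convention, keeping silent electrodes isolated instead of
propagating NaNs.

Methods
-------
pearson
    Pearson correlation of the 0/1 rows (equals the phi coefficient of the
    2x2 contingency table for binary data).
spearman
    Pearson correlation of the rank-transformed rows.
canonical
    First sparse canonical correlation between lag-embedded copies of the two
    rows (lags 0..5 bins, soft-threshold sparsity).  A pairwise CCA of two
    univariate series would degenerate to |pearson|; the lag embedding keeps a
    genuinely multivariate statistic while remaining pairwise.  This
    construction is a documented stand-in and is pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import sparse
from scipy.stats import rankdata

from .windowing import BinnedMatrix

METHODS = ("pearson", "spearman", "canonical")


@dataclass
class ConnectivityGraph:
    """Symmetric correlation matrix and its thresholded binary adjacency."""

    corr: np.ndarray
    method: str
    threshold: float = 0.5
    adjacency: np.ndarray | None = None
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        n = self.corr.shape[0]
        if self.corr.shape != (n, n):
            raise ValueError("corr must be square")
        if self.node_ids is None:
            self.node_ids = np.arange(n)
        else:
            self.node_ids = np.asarray(self.node_ids, dtype=int)

    @property
    def n_nodes(self) -> int:
        return self.corr.shape[0]


def _pearson_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation with the zero-variance -> 0 convention."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    ss = np.einsum("ij,ij->i", Xc, Xc)
    corr = Xc @ Xc.T
    denom = np.sqrt(np.outer(ss, ss))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, corr / denom, 0.0)
    zero_var = ss <= 0
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def _binary_pearson(X: np.ndarray) -> np.ndarray:
    """Pearson of 0/1 rows via the phi-coefficient closed form.

    Exploits sparsity of the co-occurrence counts; algebraically identical to
    :func:`_pearson_rows` on binary input but much faster for long windows.
    """
    T = X.shape[1]
    r = X.sum(axis=1).astype(float)
    S = sparse.csr_matrix(X)
    n11 = np.asarray((S @ S.T).todense(), dtype=float)
    num = n11 * T - np.outer(r, r)
    var = r * (T - r)
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(denom > 0, num / denom, 0.0)
    zero_var = var <= 0
    corr[zero_var, :] = 0.0
    corr[:, zero_var] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def _lag_embed(x: np.ndarray, lags: int) -> np.ndarray:
    T = x.size - lags
    return np.stack([x[l : l + T] for l in range(lags + 1)], axis=1)


def _soft_unit(v: np.ndarray, lam: float) -> np.ndarray:
    thr = lam * np.max(np.abs(v)) if v.size else 0.0
    s = np.sign(v) * np.maximum(np.abs(v) - thr, 0.0)
    n = np.linalg.norm(s)
    return s / n if n > 0 else np.full_like(v, 1.0 / np.sqrt(v.size))

def _sparse_cca_pair(
    xi: np.ndarray, xj: np.ndarray, lags: int, lam: float, n_iter: int = 30
) -> float:
    """First sparse canonical correlation of lag-embedded binary rows."""
    A = _lag_embed(xi, lags)
    B = _lag_embed(xj, lags)
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    sa = A.std(axis=0)
    sb = B.std(axis=0)
    if not sa.any() or not sb.any():
        return 0.0
    A = A[:, sa > 0] / sa[sa > 0]
    B = B[:, sb > 0] / sb[sb > 0]
    C = A.T @ B / A.shape[0]
    u = np.full(C.shape[0], 1.0 / np.sqrt(C.shape[0]))
    v = np.full(C.shape[1], 1.0 / np.sqrt(C.shape[1]))
    for _ in range(n_iter):
        v = _soft_unit(C.T @ u, lam)
        u = _soft_unit(C @ v, lam)
    a = A @ u
    b = B @ v
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(abs(a @ b) / denom)


def correlate(
    binned: BinnedMatrix,
    method: str = "pearson",
    cca_lags: int = 5,
    cca_sparsity: float = 0.1,
) -> ConnectivityGraph:
    """Pairwise correlation matrix of the binned rows (adjacency unset)."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    X = binned.values.astype(float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 electrodes to correlate")
    if method == "pearson":
        is_binary = np.isin(np.unique(X), (0.0, 1.0)).all()
        corr = _binary_pearson(binned.values) if is_binary else _pearson_rows(X)
    elif method == "spearman":
        corr = _pearson_rows(rankdata(X, axis=1))
    else:
        n = X.shape[0]
        corr = np.eye(n)
        variant = X.std(axis=1) > 0
        for i in range(n):
            for j in range(i + 1, n):
                if variant[i] and variant[j]:
                    corr[i, j] = corr[j, i] = _sparse_cca_pair(
                        X[i], X[j], cca_lags, cca_sparsity
                    )
        corr = np.clip(corr, -1.0, 1.0)
    return ConnectivityGraph(corr, method, node_ids=binned.electrode_ids)


def binarize(corr: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Edge (i, j) iff corr[i, j] >= threshold (signed rule); no self-loops."""
    corr = np.asarray(corr, dtype=float)
    adjacency = (corr >= threshold).astype(np.uint8)
    np.fill_diagonal(adjacency, 0)
    return adjacency


def build_graph(
    binned: BinnedMatrix, method: str = "pearson", threshold: float = 0.5
) -> ConnectivityGraph:
    """Correlate and binarize in one step."""
    graph = correlate(binned, method)
    return replace(graph, threshold=threshold, adjacency=binarize(graph.corr, threshold))
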