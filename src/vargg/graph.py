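"""Spatial kNN adjacency and composite-weight expression augmentation.

The neighborhood model: a binary spatial adjacency W_s marks each spot's k
nearest neighbors (Euclidean, self excluded, ties broken by lower index); a
cosine-dissimilarity expression weight W_g and an optionally available
normalized-Euclidean morphology weight W_m are evaluated on that support; the
composite W_all is their elementwise product and gates how much of each
neighbor's expression profile is added to a spot during augmentation:

    X'_i = X_i + alpha * sum_j W_all[i, j] * X_j

Weights are materialized only on the edge support (sparse contract); dense
export is provided for small graphs and debugging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.spatial.distance import cdist
from sklearn.neighbors import BallTree, KDTree

from .errors import ConsistencyError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryAdjacency",
    "WeightMatrix",
    "build_adjacency",
    "expression_dissimilarity",
    "morphology_dissimilarity",
    "composite_weights",
    "augment_expression",
]

_DENSE_LIMIT = 2000


@dataclass
class BinaryAdjacency:
    """kNN indicator graph over spots; edges are ordered (i, j) pairs."""

    n: int
    edges: np.ndarray  # (E, 2) int
    k: int
    method: str
    symmetrized: bool

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n:
                raise ConsistencyError("edge index out of range")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ConsistencyError("self-loops are not allowed")

    def edge_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, self.edges.tolist()))

    def symmetrize(self) -> "BinaryAdjacency":
        """Union with the reversed edges (logical OR) for undirected use."""
        if self.symmetrized:
            return self
        both = np.vstack([self.edges, self.edges[:, ::-1]])
        both = np.unique(both, axis=0)
        return BinaryAdjacency(self.n, both, self.k, self.method, True)

    def to_dense(self) -> np.ndarray:
        if self.n > _DENSE_LIMIT:
            raise ParameterError(f"dense export limited to n <= {_DENSE_LIMIT}")
        A = np.zeros((self.n, self.n))
        if self.edges.size:
            A[self.edges[:, 0], self.edges[:, 1]] = 1.0
        return A


@dataclass
class WeightMatrix:
    """Pairwise weights on a sparse support of ordered spot pairs."""

    n: int
    support: np.ndarray  # (E, 2) int
    weights: np.ndarray  # (E,) float
    kind: str  # spatial | expression | morphology | composite

    def __post_init__(self):
        self.support = np.asarray(self.support, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if self.support.shape[0] != self.weights.shape[0]:
            raise ConsistencyError("support/weights length mismatch")
        if self.weights.size and not np.all(np.isfinite(self.weights)):
            raise ConsistencyError("weights must be finite")

    def to_sparse(self) -> scipy.sparse.csr_matrix:
        return scipy.sparse.coo_matrix(
            (self.weights, (self.support[:, 0], self.support[:, 1])),
            shape=(self.n, self.n)).tocsr()

    def to_dense(self) -> np.ndarray:
        if self.n > _DENSE_LIMIT:
            raise ParameterError(f"dense export limited to n <= {_DENSE_LIMIT}")
        return self.to_sparse().toarray()

    def to_tsv(self, path) -> None:
        pd.DataFrame({"i": self.support[:, 0], "j": self.support[:, 1],
                      "weight": self.weights}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n: int, kind: str) -> "WeightMatrix":
        df = pd.read_csv(path, sep="\t")
        return cls(n, df[["i", "j"]].to_numpy(), df["weight"].to_numpy(), kind)


# ---------------------------------------------------------------------------
# Adjacency construction
# ---------------------------------------------------------------------------

def _candidate_neighbors(coords: np.ndarray, kq: int, method: str):
    """Distances and indices of the kq nearest points per row (self included)."""
    if method == "kdtree":
        dist, idx = KDTree(coords).query(coords, k=kq)
    elif method == "balltree":
        dist, idx = BallTree(coords).query(coords, k=kq)
    elif method == "brute_euclidean":
        D = cdist(coords, coords)
        idx = np.argsort(D, axis=1, kind="stable")[:, :kq]
        dist = np.take_along_axis(D, idx, axis=1)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return dist, idx


def build_adjacency(coords: np.ndarray, k: int = 6, method: str = "kdtree",
                    symmetrize: bool = False) -> BinaryAdjacency:
    """k-nearest-neighbor indicator adjacency by Euclidean distance.

    All three construction methods (kdtree, balltree, brute_euclidean) return
    identical edge sets; distance ties are broken by lower spot index so the
    result is deterministic. Optional symmetrization is by logical OR.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 spots")
    if not np.all(np.isfinite(coords)):
        raise ParameterError("coordinates must be finite")
    if k < 0 or k >= n:
        raise ParameterError(f"k={k} must satisfy 0 <= k <= N-1={n - 1}")
    if k == 0:
        return BinaryAdjacency(n, np.empty((0, 2), int), 0, method, symmetrize)

    kq = min(n, k + 2)
    while True:
        dist, idx = _candidate_neighbors(coords, kq, method)
        rows = []
        need_expand = False
        for i in range(n):
            mask = idx[i] != i
            d_i, j_i = dist[i][mask], idx[i][mask]
            order = np.lexsort((j_i, d_i))  # distance first, then lower index
            d_i, j_i = d_i[order], j_i[order]
            if kq < n and d_i.size >= k and d_i.size > k and d_i[k - 1] == d_i[-1]:
                # tie group may extend past the candidate window
                need_expand = True
                break
            if kq < n and d_i.size < k:
                need_expand = True
                break
            rows.append(j_i[:k])
        if not need_expand:
            break
        kq = min(n, kq * 2)
    src = np.repeat(np.arange(n), k)
    dst = np.concatenate(rows)
    adj = BinaryAdjacency(n, np.column_stack([src, dst]), k, method, False)
    return adj.symmetrize() if symmetrize else adj


# ---------------------------------------------------------------------------
# Edge weights
# ---------------------------------------------------------------------------

def expression_dissimilarity(X: np.ndarray, support: np.ndarray,
                             mode: str = "dissimilarity") -> WeightMatrix:
    """Cosine dissimilarity 1 - cos(X_i, X_j) on the supplied pair support.

    Pairs where either vector has zero norm get weight 1 (maximally
    dissimilar by convention). ``mode='similarity'`` returns the cosine
    similarity instead — a deliberate alternative to the printed
    dissimilarity form, which up-weights dissimilar neighbors.
    """
    X = np.asarray(X, dtype=float)
    if mode not in ("dissimilarity", "similarity"):
        raise ParameterError(f"unknown expression weight mode {mode!r}")
    support = np.asarray(support, dtype=int).reshape(-1, 2)
    norms = np.linalg.norm(X, axis=1)
    i, j = support[:, 0], support[:, 1]
    denom = norms[i] * norms[j]
    dots = np.einsum("ij,ij->i", X[i], X[j]) if support.size else np.empty(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
    w = cos if mode == "similarity" else 1.0 - cos
    return WeightMatrix(X.shape[0], support, w, "expression")


def morphology_dissimilarity(F: np.ndarray, support: np.ndarray) -> WeightMatrix:
    """1 - d_ij / max(d) with Euclidean d over the supplied support.

    max(d) is taken over the pairs actually weighted (the kNN support), not
    all N^2 pairs. If every supported distance is zero, all weights are 1.
    """
    F = np.asarray(F, dtype=float)
    support = np.asarray(support, dtype=int).reshape(-1, 2)
    if support.size == 0:
        raise ParameterError("morphology weights need a non-empty support")
    d = np.linalg.norm(F[support[:, 0]] - F[support[:, 1]], axis=1)
    dmax = d.max()
    if dmax == 0:
        logger.warning("all supported morphology distances are zero; weights set to 1")
        w = np.ones_like(d)
    else:
        w = 1.0 - d / dmax
    return WeightMatrix(F.shape[0], support, w, "morphology")


def composite_weights(Ws: BinaryAdjacency, Wg: WeightMatrix,
                      Wm: WeightMatrix | None = None) -> WeightMatrix:
    """Elementwise product W_s * W_g (* W_m) on the spatial support.

    Off the spatial support the composite weight is zero by construction;
    the morphology factor is dropped when unavailable.
    """
    support = Ws.edges
    key = lambda arr: {tuple(p): idx for idx, p in enumerate(arr.tolist())}
    wg_index = key(Wg.support)
    if Wg.n != Ws.n or (Wm is not None and Wm.n != Ws.n):
        raise ConsistencyError("operand spot counts differ")
    wm_index = key(Wm.support) if Wm is not None else None
    w = np.empty(support.shape[0])
    for e, pair in enumerate(map(tuple, support.tolist())):
        if pair not in wg_index:
            raise ConsistencyError(f"pair {pair} missing from expression weights")
        val = Wg.weights[wg_index[pair]]
        if wm_index is not None:
            if pair not in wm_index:
                raise ConsistencyError(f"pair {pair} missing from morphology weights")
            val *= Wm.weights[wm_index[pair]]
        w[e] = val
    return WeightMatrix(Ws.n, support.copy(), w, "composite")


def augment_expression(X: np.ndarray, Wall: WeightMatrix,
                       alpha: float) -> np.ndarray:
    """Neighborhood-weighted expression augmentation.

    X'_i = X_i + alpha * sum_j Wall[i, j] * X_j. No row normalization is
    applied; alpha = 0 returns X unchanged.
    """
    if alpha < 0:
        raise ParameterError("alpha must be >= 0")
    X = np.asarray(X, dtype=float)
    if Wall.n != X.shape[0]:
        raise ConsistencyError("weight matrix and expression spot counts differ")
    return X + alpha * (Wall.to_sparse() @ X)
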