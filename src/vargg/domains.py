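"""Leiden domain calling on the latent space and clustering evaluation.

External agreement metrics (ARI, NMI) are computed from the contingency
table of the two partitions; internal indices (silhouette, Davies-Bouldin,
Calinski-Harabasz) are delegated to scikit-learn. Leiden runs on a kNN graph
of the latent matrix via leidenalg; when a target domain count is given the
resolution is found by bisection.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
from sklearn.metrics import (calinski_harabasz_score, davies_bouldin_score,
                             silhouette_score)
from sklearn.neighbors import NearestNeighbors

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "DomainResult",
    "ContingencyTable",
    "leiden_domains",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "internal_indices",
    "write_metrics_json",
]


@dataclass
class DomainResult:
    """Per-spot domain labels plus the metric bundle."""

    labels: np.ndarray
    n_domains: int
    resolution_used: float
    metrics: dict | None = None


@dataclass
class ContingencyTable:
    """Joint counts n_ij of two partitions, with margins."""

    counts: np.ndarray  # (c_U, c_V)
    row_sums: np.ndarray
    col_sums: np.ndarray
    n: int

    @classmethod
    def from_labels(cls, a, b) -> "ContingencyTable":
        a = np.asarray(a)
        b = np.asarray(b)
        if a.shape != b.shape or a.ndim != 1:
            raise InputError("label vectors must be 1-D and equal length")
        if a.size < 2:
            raise InputError("need at least 2 samples")
        _, ai = np.unique(a, return_inverse=True)
        _, bi = np.unique(b, return_inverse=True)
        counts = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
        np.add.at(counts, (ai, bi), 1)
        return cls(counts, counts.sum(axis=1), counts.sum(axis=0), int(a.size))


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x * (x - 1.0) / 2.0


def adjusted_rand_index(a, b) -> float:
    """Chance-adjusted agreement between two partitions; 1 when identical."""
    ct = ContingencyTable.from_labels(a, b)
    sum_ij = _comb2(ct.counts).sum()
    sum_i = _comb2(ct.row_sums).sum()
    sum_j = _comb2(ct.col_sums).sum()
    total = _comb2(np.array([ct.n]))[0]
    expected = sum_i * sum_j / total
    max_index = 0.5 * (sum_i + sum_j)
    if max_index == expected:  # both partitions trivial -> identical
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def normalized_mutual_information(a, b) -> float:
    """2 MI / (H(U) + H(V)) with natural logs; in [0, 1].

    Zero-probability cells contribute 0 (the x log x -> 0 limit). Two
    identical single-cluster partitions have H(U) = H(V) = 0; that 0/0 case
    is defined as 1.0.
    """
    ct = ContingencyTable.from_labels(a, b)
    p = ct.counts / ct.n
    pi = ct.row_sums / ct.n
    pj = ct.col_sums / ct.n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = p / np.outer(pi, pj)
        mi = float(np.nansum(np.where(p > 0, p * np.log(ratio), 0.0)))
    h_u = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    h_v = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))
    if h_u + h_v == 0.0:
        logger.info("both partitions are single clusters; NMI defined as 1.0")
        return 1.0
    return 2.0 * mi / (h_u + h_v)


def _knn_igraph(Z: np.ndarray, knn: int) -> ig.Graph:
    n = Z.shape[0]
    k = min(knn, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Z)
    _, idx = nn.kneighbors(Z)
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1:].reshape(-1)
    pairs = np.unique(np.sort(np.column_stack([src, dst]), axis=1), axis=0)
    g = ig.Graph(n=n, edges=pairs.tolist(), directed=False)
    return g


def _run_leiden(g: ig.Graph, resolution: float, seed: int,
                objective: str) -> np.ndarray:
    # n_iterations=-1 runs the Leiden moves to convergence, which gives
    # markedly cleaner partitions than a fixed small iteration count
    if objective == "modularity":
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution, seed=seed, n_iterations=-1)
    elif objective == "cpm":
        part = leidenalg.find_partition(
            g, leidenalg.CPMVertexPartition,
            resolution_parameter=resolution, seed=seed, n_iterations=-1)
    else:
        raise ParameterError(f"unknown Leiden objective {objective!r}")
    return np.asarray(part.membership, dtype=int)


def leiden_domains(Z: np.ndarray, knn: int = 15,
                   resolution: float | None = None,
                   target_domains: int | None = None,
                   seed: int = 0, objective: str = "modularity") -> DomainResult:
    """Leiden clustering of the latent matrix.

    A kNN graph (Euclidean) over rows of ``Z`` is partitioned by Leiden at
    the given resolution. If ``target_domains`` is given instead, resolution
    is searched by bisection in [0.05, 3.0] (at most 30 iterations) and the
    labeling whose domain count is closest to the target is returned (ties
    broken toward the lower resolution).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] < 2:
        raise ParameterError("need at least 2 spots")
    if (resolution is None) == (target_domains is None):
        raise ParameterError("give exactly one of resolution / target_domains")
    g = _knn_igraph(Z, knn)
    if resolution is not None:
        labels = _run_leiden(g, resolution, seed, objective)
        return DomainResult(labels, int(labels.max()) + 1, float(resolution))

    lo, hi = 0.05, 3.0
    best = None  # (|count - target|, resolution, labels, count)
    for res in (lo, hi):
        labels = _run_leiden(g, res, seed, objective)
        cnt = int(labels.max()) + 1
        cand = (abs(cnt - target_domains), res, labels, cnt)
        if best is None or cand[:2] < best[:2]:
            best = cand
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        labels = _run_leiden(g, mid, seed, objective)
        cnt = int(labels.max()) + 1
        cand = (abs(cnt - target_domains), mid, labels, cnt)
        if cand[:2] < best[:2]:
            best = cand
        if cnt == target_domains:
            break
        if cnt < target_domains:
            lo = mid
        else:
            hi = mid
    if best[3] != target_domains:
        logger.warning("bisection reached %d domains (target %d)",
                       best[3], target_domains)
    return DomainResult(best[2], best[3], best[1])


_NOT_COMPUTABLE = float("nan")


def internal_indices(Z: np.ndarray, labels) -> dict:
    """Silhouette, Davies-Bouldin, and Calinski-Harabasz on ``Z``.

    With fewer than 2 clusters the indices are undefined and a NaN marker is
    returned for each rather than raising.
    """
    Z = np.asarray(Z, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        logger.warning("single cluster: internal indices not computable")
        return {"SC": _NOT_COMPUTABLE, "DBI": _NOT_COMPUTABLE,
                "CH": _NOT_COMPUTABLE}
    return {
        "SC": float(silhouette_score(Z, labels, metric="euclidean")),
        "DBI": float(davies_bouldin_score(Z, labels)),
        "CH": float(calinski_harabasz_score(Z, labels)),
    }


def write_metrics_json(path, metrics: dict) -> None:
    clean = {k: (None if isinstance(v, float) and math.isnan(v) else v)
             for k, v in metrics.items()}
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True)
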