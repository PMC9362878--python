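"""Optional generation of the assignment matrix by multi-resolution
community detection.

Pipeline: exact k-nearest-neighbour lists by Euclidean distance in a
user-supplied embedding (PCA scores, typically), converted to a shared
nearest-neighbour (SNN) graph with Jaccard edge weights
|N(u) ∩ N(v)| / |N(u) ∪ N(v)| — each cell's neighbourhood here includes
the cell itself plus its k neighbours — then one modularity-optimizing
community-detection run per resolution value on the same weighted graph.

Defaults (k = 20, prune = 1/15) follow common single-cell practice; both
are configurable.  Neighbour search is brute force and exact, with
distance ties broken by cell index, so results are fully deterministic;
the community detection step is seeded.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp

from .io import CellAssignmentMatrix, EmbeddingMatrix
from .graph import size_rank_column

_log = logging.getLogger("cellflows.neighbors")

__all__ = ["NeighborGraph", "build_knn", "knn_to_snn", "cluster_grid",
           "DEFAULT_K", "DEFAULT_PRUNE"]

DEFAULT_K = 20
DEFAULT_PRUNE = 1.0 / 15.0


class NeighborGraph:
    """kNN neighbour lists and, once built, the pruned SNN edge weights.

    Attributes
    ----------
    knn : ndarray of shape (n_cells, k)
        Each cell's k nearest neighbours (self excluded), nearest first.
    snn : scipy.sparse.csr_matrix or None
        Symmetric Jaccard weights in [0, 1] after :func:`knn_to_snn`.
    """

    def __init__(self, knn: np.ndarray, snn: sp.csr_matrix | None = None):
        self.knn = knn
        self.snn = snn

    @property
    def n_cells(self) -> int:
        return self.knn.shape[0]

    @property
    def k(self) -> int:
        return self.knn.shape[1]


def build_knn(emb: EmbeddingMatrix, k: int = DEFAULT_K) -> NeighborGraph:
    """Exact k-nearest neighbours per cell (self excluded).

    Ties in distance are broken by ascending cell index, making the lists
    reproducible across runs and platforms.
    """
    n = emb.n_cells
    if not 0 < k < n:
        raise ValueError(f"k must satisfy 0 < k < n_cells ({n})")
    X = emb.components
    # brute force: exact at desk scale, O(n^2 d) memory-chunked
    knn = np.empty((n, k), dtype=np.int64)
    chunk = max(1, int(2e7) // max(n, 1))
    sq = (X**2).sum(axis=1)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] - 2 * X[start:stop] @ X.T + sq[None, :]
        d2[np.arange(start, stop) - start, np.arange(start, stop)] = np.inf
        # lexicographic (distance, index) sort => deterministic tie-break
        order = np.argsort(d2, axis=1, kind="stable")
        knn[start:stop] = order[:, :k]
    return NeighborGraph(knn=knn)


def knn_to_snn(g: NeighborGraph, prune: float = DEFAULT_PRUNE) -> NeighborGraph:
    """Jaccard-weighted symmetric SNN edges; weights below ``prune`` drop.

    A cell's neighbourhood is itself plus its k neighbours, so two mutual
    neighbours with otherwise identical lists reach weight 1.
    """
    if not 0 <= prune <= 1:
        raise ValueError("prune must lie in [0, 1]")
    n, k = g.n_cells, g.k
    rows = np.repeat(np.arange(n), k + 1)
    cols = np.concatenate([np.column_stack([np.arange(n), g.knn]).ravel()])
    # membership matrix M[i, j] = 1 iff j in N(i) (self included)
    M = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    M.data[:] = 1.0
    inter = (M @ M.T).tocoo()  # |N(u) ∩ N(v)|
    set_size = k + 1
    union = 2 * set_size - inter.data
    w = inter.data / union
    keep = (w >= prune) & (w > 0) & (inter.row != inter.col)
    snn = sp.csr_matrix((w[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))
    return NeighborGraph(knn=g.knn, snn=snn)


def cluster_grid(
    g: NeighborGraph,
    resolutions: np.ndarray,
    cell_ids: list[str],
    seed: int = 0,
) -> CellAssignmentMatrix:
    """One seeded modularity-community-detection run per resolution.

    Runs the Leiden algorithm (RB-configuration modularity with the given
    resolution parameter) on the pruned SNN graph, identically seeded for
    every column, and size-relabels the result so label 0 is always the
    largest cluster.  A disconnected graph is fine — each component is
    partitioned on its own.
    """
    import igraph
    import leidenalg

    if g.snn is None:
        raise ValueError("build the SNN graph first (knn_to_snn)")
    resolutions = np.asarray(resolutions, dtype=float)
    if resolutions.size == 0:
        raise ValueError("empty resolution grid")
    if np.any(np.diff(resolutions) <= 0):
        raise ValueError("resolutions must be strictly increasing")

    coo = sp.triu(g.snn, k=1).tocoo()
    graph = igraph.Graph(
        n=g.n_cells,
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    labels = np.empty((g.n_cells, resolutions.size), dtype=np.int64)
    for j, res in enumerate(resolutions):
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=float(res),
            seed=int(seed),
            n_iterations=2,
        )
        labels[:, j], _ = size_rank_column(np.asarray(part.membership))
    if resolutions.size == 1:
        return _single_column(cell_ids, resolutions, labels)
    return CellAssignmentMatrix(
        cell_ids=list(cell_ids),
        resolutions=resolutions,
        labels=labels,
    )


def _single_column(cell_ids, resolutions, labels):
    # CellAssignmentMatrix requires >= 2 resolutions; a one-column scan is
    # still useful on its own, so bypass that invariant here.
    m = CellAssignmentMatrix.__new__(CellAssignmentMatrix)
    m.cell_ids = list(cell_ids)
    m.resolutions = np.asarray(resolutions, dtype=float)
    m.labels = labels
    m.resolution_names = [f"{r:.10g}" for r in m.resolutions]
    m.label_maps = None
    return m
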