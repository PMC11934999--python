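"""k-nearest-neighbor graphs feeding the graph attention autoencoder.

Cells are connected by expression similarity (Euclidean distance on the
CPM+log2 layer); spots are connected by spatial distance between their
coordinates. Every node's neighborhood includes the node itself, so the
attention softmax is always well defined. Ties are broken by lower index,
which makes both constructions deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .io import ExpressionMatrix, SpotGeometry, ValidationError

__all__ = ["AdjacencyGraph", "build_expression_knn_graph", "build_spatial_graph"]

logger = logging.getLogger(__name__)


@dataclass
class AdjacencyGraph:
    """Neighbor lists with self-loops, A_i = kNN(i) + {i}."""

    n_nodes: int
    neighbors: list[np.ndarray]

    def __post_init__(self):
        if len(self.neighbors) != self.n_nodes:
            raise ValidationError("one neighbor set per node required")
        cleaned = []
        for i, nb in enumerate(self.neighbors):
            nb = np.unique(np.append(np.asarray(nb, dtype=int), i))
            if nb.min() < 0 or nb.max() >= self.n_nodes:
                raise ValidationError(f"neighbor index out of range at node {i}")
            cleaned.append(nb)
        self.neighbors = cleaned

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flattened (query i, neighbor j) edge lists, grouped by i."""
        src = np.concatenate([np.full(len(nb), i) for i, nb in enumerate(self.neighbors)])
        dst = np.concatenate(self.neighbors)
        return src, dst

    @property
    def n_edges(self) -> int:
        return sum(len(nb) for nb in self.neighbors)


def _knn_indices(X: np.ndarray, k: int) -> list[np.ndarray]:
    """k nearest rows per row (self excluded), Euclidean, ties by lower index."""
    n = X.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be smaller than the number of nodes ({n})")
    if k < 0:
        raise ValidationError("k must be non-negative")
    if k == 0:
        return [np.array([], dtype=int) for _ in range(n)]
    if n <= 4096:
        # exact distances let us enforce the lower-index tie rule precisely
        sq = (X * X).sum(1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
        np.fill_diagonal(d2, np.inf)
        order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
        return [order[i, :k] for i in range(n)]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    out = []
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        out.append(row)
    return out


def build_expression_knn_graph(E: ExpressionMatrix, k: int = 15) -> AdjacencyGraph:
    """Connect each cell to its k nearest cells in expression space."""
    if E.layer != "cpm_log2":
        raise ValidationError("expression graph expects the normalized layer")
    if k <= 0:
        raise ValidationError("k must be positive")
    nbrs = _knn_indices(E.values, k)
    return AdjacencyGraph(E.n_rows, nbrs)


def build_spatial_graph(G: SpotGeometry, k: int = 6) -> AdjacencyGraph:
    """Connect each spot to its k spatially nearest spots."""
    n = len(G.spot_ids)
    if k >= n and not (n == 1 and k == 0):
        raise ValidationError(f"k={k} must be smaller than the number of spots ({n})")
    uniq = {tuple(c) for c in np.round(G.coords, 12).tolist()}
    if len(uniq) < n:
        logger.warning("duplicate spot coordinates; neighbor ties broken by index")
    nbrs = _knn_indices(G.coords, k)
    return AdjacencyGraph(n, nbrs)
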