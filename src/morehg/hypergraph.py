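"""kNN hyperedge groups, incidence fusion, and the propagation operator.

Each modality contributes one hyperedge per sample: the hyperedge centred
on vertex ``j`` contains ``j`` and its ``k-1`` nearest other vertices under
the chosen metric (so every hyperedge has cardinality ``k``, counting the
centre; ``k=1`` gives the identity incidence). The per-modality N x N
incidence matrices are fused by column-wise concatenation into one global
N x (I*N) incidence, from which the symmetric degree-normalized operator

    G = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}

drives hypergraph convolution. With unit edge weights G has spectral
radius 1 and fixes the vector D_v^{1/2} 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class IncidenceStructure:
    """Binary vertex x hyperedge incidence with hyperedge weights."""

    H: np.ndarray
    edge_weights: np.ndarray
    vertex_ids: list[str]

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.float64)
        self.edge_weights = np.asarray(self.edge_weights, dtype=np.float64)
        if self.H.ndim != 2:
            raise ValueError("H must be 2-D")
        if not np.isin(self.H, (0.0, 1.0)).all():
            raise ValueError("H entries must be 0 or 1")
        if self.edge_weights.shape != (self.H.shape[1],):
            raise ValueError("one weight per hyperedge required")
        if (self.edge_weights <= 0).any():
            raise ValueError("edge weights must be positive")
        if len(self.vertex_ids) != self.H.shape[0]:
            raise ValueError("one vertex id per row required")

    @property
    def n_vertices(self) -> int:
        return self.H.shape[0]

    @property
    def n_edges(self) -> int:
        return self.H.shape[1]

    @property
    def vertex_degrees(self) -> np.ndarray:
        """d(v) = sum_e w(e) h(v, e)."""
        return self.H @ self.edge_weights

    @property
    def edge_degrees(self) -> np.ndarray:
        """d(e) = sum_v h(v, e)."""
        return self.H.sum(axis=0)


@dataclass
class PropagationOperator:
    """The N x N symmetric operator G used by hypergraph convolution."""

    G: np.ndarray
    vertex_ids: list[str]


def knn_hyperedges(
    values: np.ndarray,
    vertex_ids: list[str],
    k: int,
    metric: str = "euclidean",
    *,
    include_self_in_k: bool = True,
) -> IncidenceStructure:
    """One hyperedge per vertex containing it and its nearest neighbours.

    ``k`` is the hyperedge cardinality including the centre vertex when
    ``include_self_in_k`` is true (the default reading); otherwise each
    hyperedge holds the centre plus ``k`` neighbours. Distance ties break
    toward the smaller vertex index, so duplicate points are handled
    deterministically. All edge weights are 1.
    """
    X = np.asarray(values, dtype=np.float64)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 vertices")
    if k < 1:
        raise ValueError("k must be >= 1")
    size = k if include_self_in_k else k + 1
    if size > n:
        raise ValueError(f"hyperedge size {size} exceeds {n} vertices")

    D = cdist(X, X, metric=metric)
    np.fill_diagonal(D, -np.inf)  # the centre always comes first
    H = np.zeros((n, n))
    idx = np.arange(n)
    for j in range(n):
        # stable (distance, index) order: ties -> smaller index
        order = np.lexsort((idx, D[j]))
        H[order[:size], j] = 1.0
    return IncidenceStructure(H, np.ones(n), list(vertex_ids))


def fuse_incidence(parts: list[IncidenceStructure]) -> IncidenceStructure:
    """Column-wise concatenation of per-modality incidence matrices."""
    if not parts:
        raise ValueError("no incidence structures to fuse")
    first = parts[0]
    for p in parts[1:]:
        if p.vertex_ids != first.vertex_ids:
            raise ValueError("vertex ids/order differ across modalities")
    H = np.concatenate([p.H for p in parts], axis=1)
    w = np.concatenate([p.edge_weights for p in parts])
    return IncidenceStructure(H, w, list(first.vertex_ids))


def build_operator(inc: IncidenceStructure) -> PropagationOperator:
    """G = D_v^{-1/2} H W D_e^{-1} H^T D_v^{-1/2}; errors on zero degrees."""
    dv = inc.vertex_degrees
    de = inc.edge_degrees
    if (dv <= 0).any():
        v = int(np.flatnonzero(dv <= 0)[0])
        raise ValueError(f"vertex {inc.vertex_ids[v]!r} (index {v}) has degree 0")
    if (de <= 0).any():
        e = int(np.flatnonzero(de <= 0)[0])
        raise ValueError(f"hyperedge {e} has degree 0")
    dv_isqrt = 1.0 / np.sqrt(dv)
    scaled = (inc.H * (inc.edge_weights / de)) @ inc.H.T  # H W De^-1 H^T
    G = dv_isqrt[:, None] * scaled * dv_isqrt[None, :]
    return PropagationOperator(G, list(inc.vertex_ids))


def build_fused_operator(
    modality_values: list[np.ndarray],
    vertex_ids: list[str],
    k: int,
    metric: str = "euclidean",
    *,
    include_self_in_k: bool = True,
) -> tuple[PropagationOperator, IncidenceStructure]:
    """Convenience: per-modality kNN hyperedges -> fusion -> operator."""
    parts = [
        knn_hyperedges(
            v, vertex_ids, k, metric, include_self_in_k=include_self_in_k
        )
        for v in modality_values
    ]
    fused = fuse_incidence(parts)
    return build_operator(fused), fused
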