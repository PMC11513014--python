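"""Spatial spot graph construction and graph-level utilities.

The spot-to-spot graph is a k-nearest-neighbor graph on the 2-D spot
coordinates, symmetrized by union so no spot is orphaned. The normalized
propagation operator D̂^{-1/2}(A+I)D̂^{-1/2} (renormalization-trick form)
drives graph convolutions; neighbor lists exclude self-loops and drive
the local-context readout used by the contrastive objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

__all__ = ["SpotGraph", "CorruptedView", "build_knn_graph", "corrupt_features", "local_context"]


@dataclass
class SpotGraph:
    """Symmetric spatial adjacency with its normalized propagation operator."""

    adjacency: sp.csr_matrix  # binary, symmetric, zero diagonal
    k: int
    norm_operator: sp.csr_matrix  # D̂^{-1/2}(A+I)D̂^{-1/2}
    neighbor_lists: list[np.ndarray]

    @property
    def n_spots(self) -> int:
        return self.adjacency.shape[0]

    def row_normalized_adjacency(self) -> sp.csr_matrix:
        """A with each row scaled to sum 1 (rows of isolated spots stay 0)."""
        deg = np.asarray(self.adjacency.sum(axis=1)).ravel()
        inv = np.divide(1.0, deg, out=np.zeros_like(deg, dtype=float), where=deg > 0)
        return sp.diags(inv) @ self.adjacency


@dataclass
class CorruptedView:
    """Row-shuffled gene features used as the negative view.

    The graph topology is untouched; only the assignment of expression
    vectors to spots is permuted, so each spot keeps its neighborhood but
    sees an unrelated expression profile.
    """

    permutation: np.ndarray
    shuffled_expr: np.ndarray


def build_knn_graph(coords: np.ndarray, k: int = 6) -> SpotGraph:
    """Build the union-symmetrized kNN graph over spot coordinates.

    Each spot is linked to its ``k`` nearest neighbors by Euclidean
    distance (ties broken by lower spot index, self excluded); the
    directed graph is then symmetrized with A = max(A_dir, A_dirᵀ). The
    default ``k=6`` matches the six physical neighbors of a Visium hex
    lattice.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) matrix")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coords contain NaN/Inf")
    n = coords.shape[0]
    if k < 1:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots n={n}")

    rows = np.empty(n * k, dtype=np.int64)
    cols = np.empty(n * k, dtype=np.int64)
    idx = np.arange(n)
    # chunked full-distance ranking: deterministic tie-break by (distance, index)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = cdist(coords[start:stop], coords)
        for i in range(start, stop):
            di = d[i - start]
            order = np.lexsort((idx, di))
            order = order[order != i][:k]
            rows[i * k : (i + 1) * k] = i
            cols[i * k : (i + 1) * k] = order

    a_dir = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    adjacency = a_dir.maximum(a_dir.T)
    adjacency.setdiag(0)
    adjacency.eliminate_zeros()
    adjacency.data[:] = 1.0

    a_hat = (adjacency + sp.identity(n, format="csr")).tocsr()
    deg = np.asarray(a_hat.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    norm_operator = (d_inv_sqrt @ a_hat @ d_inv_sqrt).tocsr()

    indptr = adjacency.indptr
    neighbor_lists = [adjacency.indices[indptr[i] : indptr[i + 1]].copy() for i in range(n)]
    return SpotGraph(adjacency=adjacency, k=k, norm_operator=norm_operator, neighbor_lists=neighbor_lists)


def corrupt_features(expr: np.ndarray, seed: int | np.random.Generator) -> CorruptedView:
    """Shuffle expression vectors among spots to form the negative view."""
    expr = np.asarray(expr)
    n = expr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    permutation = rng.permutation(n)
    return CorruptedView(permutation=permutation, shuffled_expr=expr[permutation])


def local_context(Z: np.ndarray, graph: SpotGraph) -> np.ndarray:
    """Per-spot local context: sigmoid of the mean embedding of direct neighbors.

    The mean excludes the spot itself. A spot with no neighbors (cannot
    occur when n > k, but handled defensively) uses its own row.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z contains NaN/Inf")
    M = graph.row_normalized_adjacency()
    means = M @ Z
    deg = np.asarray(graph.adjacency.sum(axis=1)).ravel()
    isolated = deg == 0
    if np.any(isolated):
        warnings.warn("isolated spots present; local context falls back to own embedding")
        means[isolated] = Z[isolated]
    return 1.0 / (1.0 + np.exp(-means))
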