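"""Clustering of fused spot embeddings into spatial domains, and
agreement metrics against reference annotations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.mixture import GaussianMixture

from .graph import SpotGraph

__all__ = ["DomainAssignment", "cluster_embedding", "score_agreement", "smooth_labels"]


@dataclass
class DomainAssignment:
    """Per-spot domain labels plus the embedding they were derived from."""

    labels: np.ndarray  # integer ids in [0, K)
    K: int
    method: str
    embedding_ref: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        used = np.unique(self.labels)
        if not np.array_equal(used, np.arange(len(used))):
            # compact to consecutive ids starting at 0
            remap = {old: new for new, old in enumerate(used)}
            self.labels = np.array([remap[v] for v in self.labels])
        self.K = int(self.labels.max()) + 1


def cluster_embedding(
    Z: np.ndarray,
    K: int,
    method: str = "gmm",
    seed: int = 0,
) -> DomainAssignment:
    """Partition spots into K domains by clustering their embeddings.

    ``gmm`` (default) fits a Gaussian mixture with a shared full
    covariance matrix across components — the common choice for latent
    embeddings of spatial transcriptomics data. ``kmeans`` and ``leiden``
    (graph community detection on an embedding kNN graph; K approximate,
    reached by adjusting resolution) are alternates. Deterministic given
    ``seed``.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if K < 1 or K > n:
        raise ValueError("K must be in [1, n_spots]")
    if np.allclose(Z.var(axis=0), 0.0):
        raise ValueError(
            "embedding has zero variance; inspect training (loss trace, seed)"
        )
    if K == 1:
        return DomainAssignment(np.zeros(n, dtype=int), 1, method, Z)

    if method == "gmm":
        gm = GaussianMixture(
            n_components=K, covariance_type="tied", random_state=seed,
            n_init=5, max_iter=300, reg_covar=1e-6,
        )
        labels = gm.fit_predict(Z)
    elif method == "kmeans":
        labels = KMeans(n_clusters=K, random_state=seed, n_init=10).fit_predict(Z)
    elif method == "leiden":
        labels = _leiden(Z, K, seed)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    return DomainAssignment(labels, K, method, Z)


def _leiden(Z: np.ndarray, K: int, seed: int, k_nn: int = 15) -> np.ndarray:
    import igraph
    import leidenalg
    from sklearn.neighbors import kneighbors_graph

    A = kneighbors_graph(Z, n_neighbors=min(k_nn, Z.shape[0] - 1), mode="connectivity")
    A = A.maximum(A.T).tocoo()
    g = igraph.Graph(n=Z.shape[0], edges=list(zip(A.row.tolist(), A.col.tolist())))
    g.simplify()
    # bisection on resolution to land near K communities
    lo, hi = 1e-3, 10.0
    labels = None
    for _ in range(30):
        res = np.sqrt(lo * hi)
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=res, seed=seed,
        )
        labels = np.array(part.membership)
        k_found = labels.max() + 1
        if k_found == K:
            break
        if k_found < K:
            lo = res
        else:
            hi = res
    return labels


def score_agreement(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """Adjusted Rand index and normalized mutual information.

    Both are invariant to relabeling of either argument; ARI is
    chance-corrected (0 expected for random assignments, 1 for identity).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError("label vectors differ in length")
    return {
        "ari": float(adjusted_rand_score(truth, pred)),
        "nmi": float(normalized_mutual_info_score(truth, pred)),
    }


def smooth_labels(labels: np.ndarray, graph: SpotGraph, iterations: int = 1) -> np.ndarray:
    """Optional spatial refinement: majority vote over graph neighbors.

    Off by default in the pipeline; each iteration replaces every spot's
    label by the most common label among itself and its direct neighbors
    (ties keep the current label).
    """
    labels = np.asarray(labels, dtype=int).copy()
    for _ in range(iterations):
        new = labels.copy()
        for i, nbrs in enumerate(graph.neighbor_lists):
            votes = np.bincount(np.append(labels[nbrs], labels[i]))
            best = np.flatnonzero(votes == votes.max())
            if labels[i] not in best:
                new[i] = best[0]
        labels = new
    return labels
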