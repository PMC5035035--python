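"""Graph-based subset detection on the full marker space.

Each cell is linked to its k nearest neighbors (Euclidean, exact), the
link strength between two cells is the Jaccard overlap of their
neighbor sets, and the resulting weighted graph is partitioned by
Louvain modularity maximization. The number of communities is emergent
— nothing about cluster size or count is assumed. Unlike the
density-based methods, this operates directly on the high-dimensional
markers, not on a 2-D embedding.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.spatial.distance import cdist

from .clusterx import ClusterResult

__all__ = ["build_knn", "jaccard_weights", "louvain_partition", "phenograph"]


def build_knn(data: np.ndarray, k: int, chunk_size: int = 2000) -> np.ndarray:
    """Exact k nearest neighbors per cell, ties broken by index.

    Returns an (n, k) integer array; self is excluded. Stable argsort on
    the distance rows makes tie handling deterministic.
    """
    x = np.asarray(data, dtype=np.float64)
    n = x.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n; got k={k}, n={n}")
    out = np.empty((n, k), dtype=np.int64)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        block = cdist(x[start:stop], x)
        block[np.arange(stop - start), np.arange(start, stop)] = np.inf  # no self
        order = np.argsort(block, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return out


def jaccard_weights(neighbor_sets: np.ndarray) -> dict[tuple[int, int], float]:
    """Jaccard similarity |NN(i) & NN(j)| / |NN(i) | NN(j)| on kNN edges.

    A pair is evaluated when either cell lists the other as a neighbor;
    zero-weight pairs are dropped, and the result is undirected
    (keys are (i, j) with i < j).
    """
    n = neighbor_sets.shape[0]
    sets = [set(map(int, row)) for row in neighbor_sets]
    weights: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in sets[i]:
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in weights:
                continue
            inter = len(sets[a] & sets[b])
            if inter == 0:
                continue
            union = len(sets[a] | sets[b])
            weights[(a, b)] = inter / union
    return weights


def louvain_partition(
    edges: dict[tuple[int, int], float] | list[tuple[int, int, float]],
    n_cells: int,
    seed: int = 0,
) -> tuple[ClusterResult, float]:
    """Weighted Louvain communities, relabeled 1..K by decreasing size.

    Isolated cells (no surviving edge) become singleton communities.
    Returns the partition and its weighted modularity on the same graph.
    """
    if isinstance(edges, dict):
        edge_list = [(i, j, w) for (i, j), w in edges.items()]
    else:
        edge_list = list(edges)
    if not edge_list:
        raise ValueError("empty edge list")
    graph = nx.Graph()
    graph.add_nodes_from(range(n_cells))
    graph.add_weighted_edges_from(edge_list)
    communities = nx.community.louvain_communities(graph, weight="weight", seed=seed)
    modularity = nx.community.modularity(graph, communities, weight="weight")
    # size-ordered labels; ties by smallest member index for determinism
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.zeros(n_cells, dtype=np.int64)
    for lab, comm in enumerate(ordered, start=1):
        for node in comm:
            labels[node] = lab
    result = ClusterResult(labels=labels, method="PhenoGraph")
    return result, float(modularity)


def phenograph(data, k: int = 30, seed: int = 0) -> ClusterResult:
    """kNN graph -> Jaccard weighting -> Louvain, on the marker matrix."""
    x = np.asarray(getattr(data, "values", data), dtype=np.float64)
    n = x.shape[0]
    if n <= k:
        raise ValueError(f"need more cells than neighbors: n={n}, k={k}")
    neighbor_sets = build_knn(x, k)
    edges = jaccard_weights(neighbor_sets)
    result, modularity = louvain_partition(edges, n_cells=n, seed=seed)
    result.params = {"k": k, "seed": seed, "modularity": modularity}
    return result
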