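"""PCA embedding, shared-nearest-neighbor graph, and community detection.

The scaled matrix is embedded with PCA, a kNN graph is built in the
embedding, edges are reweighted by the Jaccard overlap of the two
endpoints' neighbor sets (the SNN graph), weak edges pruned, and
communities detected by Leiden modularity optimization with a
resolution parameter (default 0.4). Clusters are finally annotated
with cell-type names by scoring canonical marker-gene sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .preprocess import NormalizedMatrix, ScaledMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterParams",
    "embed_pca",
    "build_snn_graph",
    "cluster_graph",
    "annotate_clusters",
]


@dataclass
class ClusterParams:
    n_pcs: int = 30
    k_neighbors: int = 20
    snn_prune: float = 1.0 / 15.0  # Jaccard cutoff; edges with weight <= this removed
    resolution: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if not 0.0 <= self.snn_prune <= 1.0:
            raise ValueError("snn_prune must be in [0, 1]")


def embed_pca(sm: ScaledMatrix, n_pcs: int = 30, seed: int = 0) -> np.ndarray:
    """Top principal components of the cells (cells x n_pcs).

    Deterministic: full SVD solver, and each component's sign is fixed
    so its largest-magnitude gene loading is positive.
    """
    X = sm.values.T  # cells x genes
    if X.shape[0] < 2:
        raise ValueError("need at least 2 cells for PCA")
    max_pcs = min(X.shape)
    if n_pcs > max_pcs:
        logger.warning("n_pcs=%d clamped to %d", n_pcs, max_pcs)
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X)
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    return scores


def build_snn_graph(embedding: np.ndarray, params: ClusterParams | None = None) -> ig.Graph:
    """Shared-nearest-neighbor graph over cells.

    Neighbor sets are the k nearest cells by Euclidean distance
    (self included); edge weight is the Jaccard overlap of the two
    sets, and edges with weight <= ``snn_prune`` are removed.
    """
    params = params or ClusterParams()
    emb = np.asarray(embedding, dtype=float)
    n = emb.shape[0]
    k = params.k_neighbors
    if n < k + 1:
        raise ValueError(f"need at least k_neighbors+1={k + 1} cells, got {n}")

    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    idx = nn.kneighbors(return_distance=False)  # k nearest others (self excluded)
    # neighbor set of i = {i} plus its k nearest others (set size k + 1)
    idx = np.column_stack([np.arange(n), idx])
    set_size = k + 1

    member = sp.csr_matrix(
        (np.ones(idx.size), (np.repeat(np.arange(n), idx.shape[1]), idx.ravel())),
        shape=(n, n),
    )
    inter = (member @ member.T).tocoo()
    mask = inter.row < inter.col
    rows, cols, shared = inter.row[mask], inter.col[mask], inter.data[mask]
    jaccard = shared / (2 * set_size - shared)
    keep = jaccard > params.snn_prune
    edges = list(zip(rows[keep].tolist(), cols[keep].tolist()))
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = jaccard[keep].tolist()
    return g


def cluster_graph(graph: ig.Graph, resolution: float = 0.4, seed: int = 0) -> np.ndarray:
    """Leiden community detection at the given resolution.

    Labels are consecutive integers ordered by descending cluster size
    (ties broken by first occurrence); deterministic given the seed.
    """
    weights = graph.es["weight"] if "weight" in graph.es.attributes() else None
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    if raw.size == 0:
        return raw
    sizes = np.bincount(raw)
    first_seen = np.full(sizes.size, raw.size)
    for i, v in enumerate(raw):
        if first_seen[v] == raw.size:
            first_seen[v] = i
    order = sorted(range(sizes.size), key=lambda v: (-sizes[v], first_seen[v]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[v] for v in raw])


def annotate_clusters(
    nm: NormalizedMatrix, cluster_ids, markers: dict[str, list[str]]
) -> dict[int, str]:
    """Assign a cell-type name to each cluster by marker-set score.

    A cluster's score for a cell type is the mean over the type's
    marker genes of the gene's mean normalized expression in the
    cluster; the argmax wins, alphabetical on ties (warned).
    """
    if not markers:
        raise ValueError("marker set is empty")
    gene_idx = nm.gene_index()
    usable: dict[str, list[int]] = {}
    for ct, genes in markers.items():
        present = [gene_idx[g] for g in genes if g in gene_idx]
        if not present:
            raise ValueError(f"no marker gene of cell type {ct!r} present in matrix")
        if len(present) < len(genes):
            missing = [g for g in genes if g not in gene_idx]
            warnings.warn(f"markers missing from matrix for {ct!r}: {missing}", stacklevel=2)
        usable[ct] = present

    cluster_ids = np.asarray(cluster_ids)
    values = nm.values.tocsr()
    out: dict[int, str] = {}
    for cl in sorted(pd.unique(cluster_ids).tolist()):
        cols = np.flatnonzero(cluster_ids == cl)
        sub = values[:, cols]
        gene_means = np.asarray(sub.mean(axis=1)).ravel()
        scores = {ct: float(np.mean(gene_means[rows])) for ct, rows in usable.items()}
        best = max(scores.values())
        winners = sorted(ct for ct, s in scores.items() if s == best)
        if len(winners) > 1:
            warnings.warn(
                f"cluster {cl}: tie between {winners}; choosing {winners[0]}", stacklevel=2
            )
        out[int(cl)] = winners[0]
    return out
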