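"""Dimensionality reduction, graph clustering and cross-sample label transfer.

The clustering path is PCA (50 components) -> kNN graph -> modularity-based
community detection (Leiden, or Louvain) with a resolution scan from 0.1 to
2.0.  Integration of a query dataset (leukapheresis) with a reference
(product) finds, for each query cell, its 7 nearest reference cells in a
shared PCA space and assigns the most frequent reference cluster among them,
breaking ties by the label of the single nearest tied-label neighbor.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import ConfigError, ExprMatrix


@dataclass
class Embedding:
    coords: np.ndarray  # cells x components
    method: str
    n_components: int
    barcodes: np.ndarray = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ConfigError("embedding contains non-finite values")
        if self.coords.shape[1] != self.n_components:
            raise ConfigError("n_components does not match coordinate width")


@dataclass
class ClusterLabeling:
    labels: np.ndarray
    resolution: float
    modularity: float
    method: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not -0.5 - 1e-9 <= self.modularity <= 1.0 + 1e-9:
            raise ConfigError(f"modularity {self.modularity} outside [-0.5, 1]")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class NeighborSet:
    """Per query cell: its k nearest reference cells (ascending distance)."""

    indices: np.ndarray    # n_query x k, indices into the reference
    distances: np.ndarray  # n_query x k
    ref_barcodes: np.ndarray = None
    k_within: int = field(default=7)


def pca(e: "ExprMatrix | np.ndarray", n_components: int = 50,
        barcodes=None) -> Embedding:
    """Centered PCA of cells (genes x cells input is transposed internally).

    Component signs are fixed so the largest-|loading| gene of each component
    is positive, making scores reproducible across runs and libraries.
    """
    if isinstance(e, ExprMatrix):
        X = e.dense().T
        barcodes = e.barcodes
    else:
        X = np.asarray(e, dtype=float)
    n_cells, n_feat = X.shape
    if n_components > min(n_cells, n_feat) - 1:
        raise ConfigError(
            f"n_components={n_components} exceeds min(genes, cells) - 1"
        )
    if np.allclose(X.var(axis=0), 0):
        raise ConfigError("constant matrix has no variance to decompose")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    for j in range(n_components):
        load = model.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1
    emb = Embedding(scores, "PCA", n_components, barcodes=barcodes)
    emb.explained_variance_ratio = model.explained_variance_ratio_
    return emb


def knn_graph(emb: Embedding, k: int = 15) -> ig.Graph:
    """Undirected kNN graph: edge when either endpoint lists the other among
    its k Euclidean nearest neighbors; weight = shared-neighbor count / k,
    with each node's neighbor set augmented by the node itself so every edge
    has positive weight."""
    if k <= 0:
        raise ConfigError("k must be positive")
    n = emb.coords.shape[0]
    if k >= n:
        raise ConfigError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb.coords)
    _, idx = nn.kneighbors(emb.coords)
    neigh = [set(row[1:].tolist()) | {i} for i, row in enumerate(idx)]
    edges, weights = [], []
    seen = set()
    for i, row in enumerate(idx):
        for j in row[1:]:
            j = int(j)
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            seen.add(key)
            edges.append(key)
            weights.append(len(neigh[i] & neigh[j]) / k)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_communities(
    g: ig.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    method: str = "leiden",
) -> ClusterLabeling:
    """Modularity-maximizing community labels at a resolution (seeded)."""
    if g.vcount() == 0:
        raise ConfigError("empty graph")
    weights = g.es["weight"] if "weight" in g.es.attributes() else None
    if method == "leiden":
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights=weights,
            resolution_parameter=resolution,
            seed=seed,
            n_iterations=2,
        )
        labels = np.array(part.membership)
    elif method == "louvain":
        ig.set_random_number_generator(random.Random(seed))
        part = g.community_multilevel(weights=weights, resolution=resolution)
        labels = np.array(part.membership)
    else:
        raise ConfigError(f"unknown method {method!r}")
    modularity = g.modularity(labels, weights=weights)
    return ClusterLabeling(labels=labels, resolution=resolution,
                           modularity=modularity, method=method)


def resolution_scan(
    g: ig.Graph,
    resolutions=None,
    seed: int = 0,
    method: str = "leiden",
    tolerance: float = 0.01,
) -> pd.DataFrame:
    """Cluster at each resolution; table of (resolution, n_clusters, modularity).

    The suggested resolution (``.attrs["suggested_resolution"]``) is the
    largest resolution whose modularity lies within ``tolerance`` of the scan
    maximum — an automatable proxy for the modularity/complexity trade-off;
    the final choice remains a config override.
    """
    if resolutions is None:
        resolutions = np.round(np.arange(0.1, 2.0 + 1e-9, 0.1), 2)
    resolutions = list(resolutions)
    if not resolutions:
        raise ConfigError("empty resolution list")
    rows = []
    for r in resolutions:
        lab = cluster_communities(g, resolution=float(r), seed=seed, method=method)
        rows.append((float(r), lab.n_clusters, lab.modularity))
    out = pd.DataFrame(rows, columns=["resolution", "n_clusters", "modularity"])
    best = out["modularity"].max()
    ok = out[out["modularity"] >= best - tolerance * abs(best)]
    out.attrs["suggested_resolution"] = float(ok["resolution"].max())
    return out


def umap_embed(emb: Embedding, seed: int = 0) -> Embedding:
    """2-D UMAP of a PCA embedding, for visualization only."""
    import umap

    model = umap.UMAP(n_components=2, random_state=seed)
    coords = model.fit_transform(emb.coords)
    return Embedding(np.asarray(coords, dtype=float), "UMAP", 2,
                     barcodes=emb.barcodes)


def batch_balanced_neighbors(
    ref: Embedding,
    query: Embedding,
    k_within: int = 7,
) -> NeighborSet:
    """For each query cell, its ``k_within`` nearest reference cells by
    Euclidean distance in the shared component space."""
    n_ref = ref.coords.shape[0]
    if k_within > n_ref:
        raise ConfigError(f"k_within={k_within} exceeds reference size {n_ref}")
    if ref.coords.shape[1] != query.coords.shape[1]:
        raise ConfigError("reference and query must share the component space")
    nn = NearestNeighbors(n_neighbors=k_within).fit(ref.coords)
    dist, idx = nn.kneighbors(query.coords)
    return NeighborSet(indices=idx, distances=dist,
                       ref_barcodes=ref.barcodes, k_within=k_within)


def transfer_labels(n: NeighborSet, ref_labels: np.ndarray) -> np.ndarray:
    """Assign each query cell the most frequent label of its neighbors.

    Ties are resolved by the label of the single nearest neighbor among the
    tied labels.
    """
    ref_labels = np.asarray(ref_labels)
    if n.indices.size == 0 or n.indices.shape[1] == 0:
        raise ConfigError("empty neighbor set")
    out = []
    for row in n.indices:
        labs = ref_labels[row]
        uniq, counts = np.unique(labs, return_counts=True)
        top = counts.max()
        tied = set(uniq[counts == top].tolist())
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            for lab in labs:  # rows are sorted by ascending distance
                if lab in tied:
                    out.append(lab)
                    break
    return np.array(out)
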