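"""Clustering and integration benchmarking of latent embeddings.

Implements the standard single-cell integration scorecard: Leiden clustering
on a Euclidean KNN graph of the embedding, NMI and ARI against ground-truth
cell types, per-type graph connectivity, and graph-based local inverse
Simpson indices for batch mixing (iLISI, higher = better mixed) and cell-type
purity (cLISI, higher = purer neighborhoods), both min-max rescaled to [0,1].

NMI uses the arithmetic-mean entropy normalization. LISI follows the
perplexity-calibrated Gaussian-kernel neighborhood weighting of the standard
integration benchmarks (perplexity 30 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.neighbors import NearestNeighbors


@dataclass
class EvalReport:
    nmi: float
    ari: float
    graph_connectivity: float
    ilisi: float
    clisi: float
    n_clusters: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _knn_indices(z: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(z)
    dist, idx = nn.kneighbors(z)
    return dist[:, 1:], idx[:, 1:]  # drop self


def leiden_cluster(
    z: np.ndarray, k_neighbors: int = 15, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on a Euclidean KNN graph of the embedding."""
    import igraph as ig
    import leidenalg

    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("embedding contains non-finite values")
    n = z.shape[0]
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1 = {k_neighbors + 1} cells, got {n}")
    _, idx = _knn_indices(z, k_neighbors)
    rows = np.repeat(np.arange(n), k_neighbors)
    cols = idx.ravel()
    edges = {(min(i, j), max(i, j)) for i, j in zip(rows, cols)}
    g = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=np.intp)


def graph_connectivity(
    z: np.ndarray, labels: np.ndarray, k_neighbors: int = 15
) -> float:
    """Mean over label classes of the largest-connected-component fraction of
    the class-induced KNN subgraph (1 = every class fully connected)."""
    labels = np.asarray(labels, dtype=object)
    _, idx = _knn_indices(np.asarray(z, dtype=np.float64), k_neighbors)
    n = z.shape[0]
    rows = np.repeat(np.arange(n), idx.shape[1])
    adj = sparse.csr_matrix(
        (np.ones(rows.size), (rows, idx.ravel())), shape=(n, n)
    )
    adj = adj + adj.T
    scores = []
    for t in sorted(set(labels)):
        cells = np.where(labels == t)[0]
        if cells.size < 2:
            warnings.warn(f"label class '{t}' has < 2 cells; excluded from connectivity")
            continue
        sub = adj[np.ix_(cells, cells)]
        n_comp, comp = csgraph.connected_components(sub, directed=False)
        largest = np.bincount(comp).max()
        scores.append(largest / cells.size)
    return float(np.mean(scores)) if scores else float("nan")


def _lisi(z: np.ndarray, labels: np.ndarray, perplexity: float = 30.0) -> np.ndarray:
    """Per-cell local inverse Simpson index of `labels` with a Gaussian kernel
    calibrated per cell to the given perplexity over its KNN neighborhood."""
    labels = np.asarray(labels, dtype=object)
    cats = {c: i for i, c in enumerate(sorted(set(labels)))}
    lab = np.array([cats[c] for c in labels])
    n = z.shape[0]
    k = min(int(3 * perplexity), n - 1)
    dist, idx = _knn_indices(np.asarray(z, dtype=np.float64), k)
    d2 = dist**2
    log_perp = np.log(perplexity)
    out = np.empty(n)
    for i in range(n):
        beta, lo, hi = 1.0, 0.0, np.inf
        di = d2[i] - d2[i].min()
        for _ in range(50):
            w = np.exp(-beta * di)
            s = w.sum()
            if s <= 0:
                beta /= 2
                continue
            p = w / s
            h = -(p[p > 0] * np.log(p[p > 0])).sum()  # entropy
            if abs(h - log_perp) < 1e-5:
                break
            if h > log_perp:  # too flat -> sharpen
                lo = beta
                beta = beta * 2 if hi == np.inf else (beta + hi) / 2
            else:
                hi = beta
                beta = (beta + lo) / 2
        w = np.exp(-beta * di)
        p = w / w.sum()
        probs = np.bincount(lab[idx[i]], weights=p, minlength=len(cats))
        out[i] = 1.0 / np.sum(probs**2)
    return out


def ilisi_score(z: np.ndarray, batch: np.ndarray, perplexity: float = 30.0) -> float:
    """Batch-mixing iLISI, rescaled (score - 1)/(B - 1) to [0, 1]."""
    batch = np.asarray(batch, dtype=object)
    b = len(set(batch))
    if b < 2:
        return float("nan")
    raw = _lisi(z, batch, perplexity).mean()
    return float((raw - 1.0) / (b - 1.0))


def clisi_score(z: np.ndarray, labels: np.ndarray, perplexity: float = 30.0) -> float:
    """Cell-type cLISI, rescaled (C - score)/(C - 1) so 1 = pure neighborhoods."""
    labels = np.asarray(labels, dtype=object)
    c = len(set(labels))
    if c < 2:
        return float("nan")
    raw = _lisi(z, labels, perplexity).mean()
    return float((c - raw) / (c - 1.0))


def evaluate_embedding(
    z: np.ndarray,
    type_labels: np.ndarray,
    batch_labels: np.ndarray,
    resolution: float = 1.0,
    k_neighbors: int = 15,
    seed: int = 0,
    perplexity: float = 30.0,
) -> EvalReport:
    """Full scorecard: Leiden clusters vs types (NMI, ARI), connectivity,
    iLISI (batch mixing) and cLISI (type purity)."""
    z = np.asarray(z, dtype=np.float64)
    type_labels = np.asarray(type_labels, dtype=object)
    batch_labels = np.asarray(batch_labels, dtype=object)
    clusters = leiden_cluster(z, k_neighbors=k_neighbors, resolution=resolution, seed=seed)
    types_codes = np.unique(type_labels.astype(str), return_inverse=True)[1]
    nmi = normalized_mutual_info_score(types_codes, clusters, average_method="arithmetic")
    ari = adjusted_rand_score(types_codes, clusters)
    gc = graph_connectivity(z, type_labels, k_neighbors=k_neighbors)
    return EvalReport(
        nmi=float(nmi),
        ari=float(ari),
        graph_connectivity=gc,
        ilisi=ilisi_score(z, batch_labels, perplexity),
        clisi=clisi_score(z, type_labels, perplexity),
        n_clusters=int(len(set(clusters))),
    )


def concat_pca_baseline(views: dict[str, np.ndarray], mask: np.ndarray,
                        modalities: list[str], n_components: int = 20,
                        seed: int = 0) -> np.ndarray:
    """Naive baseline: concatenate all modality views (zeros where a modality
    is missing) and project with PCA to the embedding dimensionality."""
    from sklearn.decomposition import PCA

    blocks = []
    for j, m in enumerate(modalities):
        v = views[m].copy()
        v[~mask[:, j]] = 0.0
        blocks.append(v)
    x = np.concatenate(blocks, axis=1)
    n_comp = min(n_components, min(x.shape) - 1)
    return PCA(n_components=n_comp, random_state=seed).fit_transform(x)


def export_umap(z: np.ndarray, path, seed: int = 0) -> None:
    """Write 2-D UMAP coordinates of the embedding to TSV (for plotting
    elsewhere; plotting itself is out of scope here)."""
    import pandas as pd
    import umap

    emb = umap.UMAP(random_state=seed).fit_transform(np.asarray(z, dtype=np.float64))
    pd.DataFrame(emb, columns=["umap_1", "umap_2"]).to_csv(path, sep="\t", index=False)
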