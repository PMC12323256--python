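"""Per-modality cosine mutual-KNN graphs and supervision sampling.

Each modality gets its own adjacency: among cells where that modality was
measured, an undirected edge joins i and j only when each is in the other's
top-k by cosine similarity (mutual KNN). Positive pairs for the contrastive
objective are edges sampled from these graphs; triplets for the
semi-supervised objective are sampled from the labeled cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .data import MISSING_LABEL, MosaicDataset, PreprocessedDataset


@dataclass
class NeighborGraph:
    """Binary symmetric adjacency per modality, zero diagonal.

    Cells unavailable in a modality have all-zero rows/columns there.
    """

    adjacency: dict[str, sparse.csr_matrix]
    k: int

    def edges(self, m: str) -> np.ndarray:
        """Undirected edge list (n_edges x 2) with i < j."""
        coo = sparse.triu(self.adjacency[m], k=1).tocoo()
        return np.column_stack([coo.row, coo.col]).astype(np.intp)

    def n_edges(self, m: str) -> int:
        return int(self.adjacency[m].nnz // 2)


@dataclass
class PairSet:
    """Contrastive positive pairs per modality; each pair is a graph edge."""

    pairs: dict[str, np.ndarray]  # modality -> (T, 2) index array
    T: int
    tau: float


@dataclass
class TripletSet:
    """(anchor, positive, negative) index triples over labeled cells."""

    triplets: np.ndarray  # (H, 3)
    H: int
    margin: float


def cosine_similarity(x_i: np.ndarray, x_j: np.ndarray) -> float:
    """Cosine similarity dot(x_i, x_j) / (|x_i| |x_j|) of two feature vectors."""
    ni, nj = np.linalg.norm(x_i), np.linalg.norm(x_j)
    if ni == 0 or nj == 0:
        raise ValueError("cosine similarity undefined for a zero-norm vector")
    return float(np.dot(x_i, x_j) / (ni * nj))


def build_mutual_knn(
    view: np.ndarray, available: np.ndarray, k: int
) -> sparse.csr_matrix:
    """Mutual-KNN adjacency over available cells by cosine similarity.

    A_ij = 1 iff j is in i's top-k (self excluded) AND i is in j's top-k.
    Ties in the top-k boundary are broken toward the lower cell index.
    Unavailable cells get all-zero rows/columns.
    """
    n = view.shape[0]
    available = np.asarray(available, dtype=bool)
    idx = np.where(available)[0]
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0 or idx.size == 0:
        return sparse.csr_matrix((n, n))
    if idx.size < k + 1:
        raise ValueError(f"need >= k+1 = {k + 1} available cells, got {idx.size}")
    sub = view[idx]
    norms = np.linalg.norm(sub, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        raise ValueError(f"all-zero available cell rows at indices {idx[zero[:5]].tolist()}")
    normed = sub / norms[:, None]
    sim = normed @ normed.T
    np.fill_diagonal(sim, -np.inf)
    na = idx.size
    # lexsort on (-sim, col-index): stable lower-index tie-break
    col = np.broadcast_to(np.arange(na), (na, na))
    order = np.lexsort((col, -sim), axis=1)[:, :k]
    knn = np.zeros((na, na), dtype=bool)
    np.put_along_axis(knn, order, True, axis=1)
    mutual = knn & knn.T
    rows, cols = np.nonzero(mutual)
    adj = sparse.csr_matrix(
        (np.ones(rows.size), (idx[rows], idx[cols])), shape=(n, n)
    )
    return adj


def build_graphs(ds: MosaicDataset, pre: PreprocessedDataset, k: int = 15) -> NeighborGraph:
    """Per-modality mutual-KNN graphs on the preprocessed views."""
    adjacency = {}
    for m in ds.modalities:
        adjacency[m] = build_mutual_knn(pre.views[m], ds.available(m), k)
    return NeighborGraph(adjacency=adjacency, k=k)


def sample_positive_pairs(
    graph: NeighborGraph, T: int, seed: int, tau: float = 0.5
) -> PairSet:
    """Draw T edges per modality uniformly with replacement as positive pairs."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    pairs: dict[str, np.ndarray] = {}
    for m, adj in graph.adjacency.items():
        edges = graph.edges(m)
        if edges.shape[0] == 0:
            warnings.warn(f"modality '{m}' has no edges; skipping pair sampling")
            continue
        choice = rng.integers(edges.shape[0], size=T)
        chosen = edges[choice].copy()
        flip = rng.random(T) < 0.5  # random edge orientation
        chosen[flip] = chosen[flip][:, ::-1]
        pairs[m] = chosen
    return PairSet(pairs=pairs, T=T, tau=tau)


def sample_triplets(
    labels: np.ndarray, H: int, seed: int, margin: float = 1.0
) -> TripletSet:
    """Sample H (anchor, positive, negative) triples from labeled cells.

    Anchor and positive share a label but are distinct cells; the negative
    carries a different label. Anchors are drawn only from classes with at
    least two members.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    labels = np.asarray(labels, dtype=object)
    labeled = np.where(labels != MISSING_LABEL)[0]
    if labeled.size == 0:
        raise ValueError("no labeled cells")
    classes: dict[str, np.ndarray] = {}
    for t in sorted({labels[i] for i in labeled}):
        classes[t] = labeled[labels[labeled] == t]
    if len(classes) < 2:
        raise ValueError("triplet sampling needs >= 2 labeled classes")
    anchor_classes = [t for t, idx in classes.items() if idx.size >= 2]
    if not anchor_classes:
        raise ValueError("no class has >= 2 labeled cells to form an anchor/positive pair")
    rng = np.random.default_rng(seed)
    out = np.empty((H, 3), dtype=np.intp)
    for i in range(H):
        t = anchor_classes[rng.integers(len(anchor_classes))]
        same = classes[t]
        a, p = rng.choice(same, size=2, replace=False)
        other = [u for u in classes if u != t]
        neg_class = other[rng.integers(len(other))]
        n_ = rng.choice(classes[neg_class])
        out[i] = (a, p, n_)
    return TripletSet(triplets=out, H=H, margin=margin)


def export_adjacency(graph: NeighborGraph, m: str, path) -> None:
    """Write modality adjacency as sparse coordinate triplets (TSV: i, j, 1)."""
    coo = graph.adjacency[m].tocoo()
    import pandas as pd

    pd.DataFrame({"i": coo.row, "j": coo.col, "v": coo.data.astype(int)}).to_csv(
        path, sep="\t", index=False
    )
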