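"""The five objective terms and their weighted total.

All losses accept autograd tensors (or plain arrays, auto-wrapped) and return
a scalar tensor; call ``.item()`` for the float. The total objective is

    L = l1*recon + l2*kl + l3*graph + l4*contrastive + l5*triplet

with the reconstruction an MSE sum over cells and available modalities, the
KL the closed-form divergence of the fused diagonal-Gaussian posterior from
the standard-normal prior, the graph term a cross-entropy tying the sigmoid
inner-product adjacency of the latent to each modality's mutual-KNN
adjacency, the contrastive term a symmetrized InfoNCE over sampled graph
edges, and the triplet term a hinge on labeled anchor/positive/negative
distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from ._autograd import Tensor, as_tensor
from .graph import NeighborGraph, PairSet, TripletSet
from .nn import GaussianPosterior


@dataclass
class LossWeights:
    """Non-negative weights for recon, KL, graph, contrastive, triplet."""

    recon: float = 1.0
    kl: float = 0.1
    graph: float = 1.0
    contrastive: float = 1.0
    triplet: float = 1.0

    def __post_init__(self):
        for name in ("recon", "kl", "graph", "contrastive", "triplet"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"weight {name} must be finite and >= 0")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.recon, self.kl, self.graph, self.contrastive, self.triplet)


@dataclass
class LossReport:
    recon: float
    kl: float
    graph: float
    contrastive: float
    triplet: float
    total: float


def recon_loss(xs: dict[str, Tensor] | Tensor, xhats: dict[str, Tensor] | Tensor) -> Tensor:
    """Sum of squared errors over cells and available modalities.

    A sum, not a mean: each cell contributes ||x_n - xhat_n||^2 and modality
    blocks add. Accepts a single matrix pair or per-modality dicts.
    """
    if not isinstance(xs, dict):
        xs, xhats = {"_": xs}, {"_": xhats}
    total: Tensor | None = None
    for m, x in xs.items():
        x = as_tensor(x)
        xh = as_tensor(xhats[m])
        if x.shape != xh.shape:
            raise ValueError(f"shape mismatch for '{m}': {x.shape} vs {xh.shape}")
        term = ((x - xh) ** 2).sum()
        total = term if total is None else total + term
    return total


def kl_loss(post: GaussianPosterior) -> Tensor:
    """KL( N(mu, diag(nu)) || N(0, I) ) summed over cells.

    Closed form 0.5 * sum_d (nu_d + mu_d^2 - 1 - log nu_d) per cell.
    """
    mu, nu = post.mean, post.variance
    return 0.5 * (nu + mu**2 - 1.0 - nu.log()).sum()


def graph_loss(
    z: Tensor,
    graph: NeighborGraph | dict[str, sparse.spmatrix],
    n_total: int | None = None,
) -> Tensor:
    """Graph cross-entropy: -(1/N) sum_m sum_ij A^m_ij log sigmoid(z_i . z_j).

    Only ordered entries with A^m_ij = 1 contribute; the reconstructed
    adjacency is the sigmoid of the latent Gram matrix. Uses the stable
    log-sigmoid so inner products of any practical magnitude stay finite.
    `n_total` overrides the 1/N denominator (used for mini-batch scaling);
    defaults to the number of rows of z.
    """
    z = as_tensor(z)
    n = z.shape[0]
    denom = float(n_total) if n_total is not None else float(n)
    adjacency = graph.adjacency if isinstance(graph, NeighborGraph) else graph
    total: Tensor | None = None
    for m, adj in adjacency.items():
        coo = sparse.coo_matrix(adj)
        if coo.nnz == 0:
            continue
        zi = z.gather_rows(coo.row)
        zj = z.gather_rows(coo.col)
        dots = (zi * zj).sum(axis=1)
        term = dots.logsigmoid().sum()
        total = term if total is None else total + term
    if total is None:
        return Tensor(0.0)
    return -(1.0 / denom) * total


def _cosine_matrix(a: Tensor, b: Tensor, eps: float = 1e-12) -> Tensor:
    an = a / ((a**2).sum(axis=1, keepdims=True) + eps).sqrt()
    bn = b / ((b**2).sum(axis=1, keepdims=True) + eps).sqrt()
    return an @ bn.T


def info_nce_loss(z: Tensor, pairs: PairSet) -> Tensor:
    """Symmetrized InfoNCE over the sampled positive pairs, summed over
    modalities.

    For pairs (a_i, b_i), i = 1..T in one modality, writing
    S_xy = cos(z_x, z_y)/tau:

        l(a_i, b_i) = S_{a_i b_i}
                      - log( sum_{j != i} exp(S_{a_i b_j})
                             + sum_j exp(S_{a_j b_i}) )

    (the second sum includes j = i, so the positive's own score appears in
    the denominator), and the modality loss is
    -(1/2T) sum_i [ l(a_i,b_i) + l(b_i,a_i) ].
    """
    z = as_tensor(z)
    if pairs.tau <= 0:
        raise ValueError("temperature tau must be positive")
    total: Tensor | None = None
    for m, pr in pairs.pairs.items():
        T = pr.shape[0]
        if T < 2:
            raise ValueError("info_nce_loss needs T >= 2 pairs per modality")
        za = z.gather_rows(pr[:, 0])
        zb = z.gather_rows(pr[:, 1])
        term = _nce_directed(za, zb, pairs.tau) + _nce_directed(zb, za, pairs.tau)
        mod_loss = -(1.0 / (2 * T)) * term
        total = mod_loss if total is None else total + mod_loss
    if total is None:
        return Tensor(0.0)
    return total


def _nce_directed(za: Tensor, zb: Tensor, tau: float) -> Tensor:
    """sum_i l(a_i, b_i) for one direction of the pair set."""
    T = za.shape[0]
    s = _cosine_matrix(za, zb) / tau  # s[i, j] = sim(a_i, b_j)/tau
    e = s.exp()
    diag_mask = np.eye(T)
    # sum_{j != i} exp(s[i, j])  (row sums minus the diagonal)
    row_off = (e * (1.0 - diag_mask)).sum(axis=1)
    # sum_j exp(s[j, i]) including j = i (column sums)
    col_all = e.sum(axis=0)
    diag = (s * diag_mask).sum(axis=1)
    return (diag - (row_off + col_all).log()).sum()


def triplet_loss(z: Tensor, triplets: TripletSet) -> Tensor:
    """Mean hinge (1/H) sum_i max(d(a,p) - d(a,n) + margin, 0), d Euclidean.

    The hinge mean is minimized (positive sign), pulling same-type cells
    together and pushing different-type cells apart by at least the margin.
    """
    z = as_tensor(z)
    tri = triplets.triplets
    za = z.gather_rows(tri[:, 0])
    zp = z.gather_rows(tri[:, 1])
    zn = z.gather_rows(tri[:, 2])
    eps = 1e-12
    d_ap = (((za - zp) ** 2).sum(axis=1) + eps).sqrt()
    d_an = (((za - zn) ** 2).sum(axis=1) + eps).sqrt()
    hinge = (d_ap - d_an + triplets.margin).clip_min(0.0)
    return hinge.mean()


def total_loss(
    recon: Tensor | float,
    kl: Tensor | float,
    graph: Tensor | float,
    contrastive: Tensor | float,
    triplet: Tensor | float,
    weights: LossWeights,
) -> Tensor:
    """Weighted sum of the five objective terms."""
    l1, l2, l3, l4, l5 = weights.as_tuple()
    return (
        l1 * as_tensor(recon)
        + l2 * as_tensor(kl)
        + l3 * as_tensor(graph)
        + l4 * as_tensor(contrastive)
        + l5 * as_tensor(triplet)
    )
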