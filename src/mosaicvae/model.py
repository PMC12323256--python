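"""End-to-end integration model with a statsmodels-style fit surface.

``MosaicIntegrationModel`` is built from a :class:`MosaicDataset`; ``fit()``
runs the training loop (mini-batch Adam on the weighted five-term objective)
and returns an :class:`IntegrationResults` carrying the batch-corrected
latent embedding (fused posterior means), the per-epoch loss history, the
fitted parameters and a ``summary()`` table.

Training is fully deterministic for a fixed seed in single-threaded mode:
initialization, shuffling, pair/triplet sampling and the reparameterization
noise all draw from independent child streams of the one seed.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field, replace
from io import BytesIO
from pathlib import Path

import numpy as np
import pandas as pd

from ._autograd import Tensor
from .data import MISSING_LABEL, MosaicDataset, PreprocessedDataset, preprocess
from .graph import NeighborGraph, PairSet, TripletSet, build_graphs
from .losses import (
    LossReport,
    LossWeights,
    graph_loss,
    info_nce_loss,
    kl_loss,
    recon_loss,
    total_loss,
    triplet_loss,
)
from .nn import Adam, ModelParams, poe_combine, reparameterize


@dataclass
class TrainConfig:
    """Hyperparameters of the optimization loop.

    ``T`` and ``H`` are the numbers of contrastive pairs and triplets drawn
    per mini-batch (capped by what the in-batch graph and labels afford);
    ``tau`` is the InfoNCE temperature and ``margin`` the triplet hinge
    margin. ``device`` is accepted for interface compatibility; computation
    is CPU numpy.
    """

    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    latent_dim: int = 20
    hidden: list[int] = field(default_factory=lambda: [128])
    k: int = 15
    T: int = 100
    H: int = 100
    tau: float = 0.5
    margin: float = 1.0
    weights: LossWeights = field(default_factory=LossWeights)
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        for name in ("epochs", "batch_size", "latent_dim", "k", "T", "H"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is implemented")

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "weights"}
        d["weights"] = self.weights.__dict__
        return json.dumps(d, indent=2)


class MosaicIntegrationModel:
    """Product-of-experts VAE for mosaic multimodal integration.

    Parameters
    ----------
    dataset : MosaicDataset
        Validated mosaic dataset (counts, mask, batch, optional labels).
    preprocessed : PreprocessedDataset, optional
        Normalized views; computed with the field-default transforms when
        omitted.
    config : TrainConfig, optional
    """

    def __init__(
        self,
        dataset: MosaicDataset,
        preprocessed: PreprocessedDataset | None = None,
        config: TrainConfig | None = None,
    ):
        self.dataset = dataset
        self.pre = preprocessed if preprocessed is not None else preprocess(dataset)
        self.config = config if config is not None else TrainConfig()
        self.graph: NeighborGraph | None = None

    @classmethod
    def from_dataset(cls, dataset: MosaicDataset, **config_kwargs) -> "MosaicIntegrationModel":
        weights = config_kwargs.pop("weights", None)
        cfg = TrainConfig(**config_kwargs)
        if weights is not None:
            cfg = replace(cfg, weights=weights)
        return cls(dataset, config=cfg)

    # ------------------------------------------------------------------ pieces
    def _build_graphs(self) -> NeighborGraph:
        if self.graph is None:
            self.graph = build_graphs(self.dataset, self.pre, k=self.config.k)
        return self.graph

    def _forward_batch(
        self,
        params: ModelParams,
        batch_idx: np.ndarray,
        rng_reparam: np.random.Generator,
        sample: bool = True,
    ):
        """Encode available modalities, PoE-fuse, sample, decode.

        Returns (posterior, z, xs, xhats, local availability indices).
        """
        ds, pre = self.dataset, self.pre
        B = batch_idx.size
        experts, expert_cells, local_avail = {}, {}, {}
        for m in ds.modalities:
            avail = ds.available(m)[batch_idx]
            loc = np.where(avail)[0]
            if loc.size == 0:
                continue
            x_m = pre.views[m][batch_idx[loc]]
            experts[m] = params.encoders[m](Tensor(x_m))
            expert_cells[m] = loc
            local_avail[m] = loc
        post = poe_combine(experts, expert_cells, B)
        z = reparameterize(post, rng_reparam) if sample else post.mean
        xs, xhats = {}, {}
        for m, loc in local_avail.items():
            z_m = z.gather_rows(loc)
            xhats[m] = params.decoders[m](z_m)
            xs[m] = Tensor(pre.views[m][batch_idx[loc]])
        return post, z, xs, xhats, local_avail

    def _batch_supervision(
        self,
        batch_idx: np.ndarray,
        induced: dict,
        rng_pairs: np.random.Generator,
        rng_tri: np.random.Generator,
        triplet_active: bool,
    ) -> tuple[PairSet | None, TripletSet | None]:
        from scipy import sparse

        cfg = self.config
        pairs = {}
        for m, adj in induced.items():
            coo = sparse.triu(adj, k=1).tocoo()
            if coo.nnz == 0:
                continue
            edges = np.column_stack([coo.row, coo.col]).astype(np.intp)
            T = min(cfg.T, max(2, coo.nnz))
            if T < 2:
                continue
            sel = rng_pairs.integers(edges.shape[0], size=T)
            chosen = edges[sel].copy()
            flip = rng_pairs.random(T) < 0.5
            chosen[flip] = chosen[flip][:, ::-1]
            pairs[m] = chosen
        pair_set = PairSet(pairs=pairs, T=cfg.T, tau=cfg.tau) if pairs else None

        tri_set = None
        if triplet_active and self.dataset.labels is not None:
            lab = self.dataset.labels[batch_idx]
            labeled = np.where(lab != MISSING_LABEL)[0]
            classes = {}
            for t in sorted({lab[i] for i in labeled}):
                classes[t] = labeled[lab[labeled] == t]
            anchor_classes = [t for t, idx in classes.items() if idx.size >= 2]
            if len(classes) >= 2 and anchor_classes:
                H = cfg.H
                out = np.empty((H, 3), dtype=np.intp)
                for i in range(H):
                    t = anchor_classes[int(rng_tri.integers(len(anchor_classes)))]
                    a, p = rng_tri.choice(classes[t], size=2, replace=False)
                    others = [u for u in classes if u != t]
                    nc = others[int(rng_tri.integers(len(others)))]
                    n_ = rng_tri.choice(classes[nc])
                    out[i] = (a, p, n_)
                tri_set = TripletSet(triplets=out, H=H, margin=cfg.margin)
        return pair_set, tri_set

    # --------------------------------------------------------------------- fit
    def fit(self, seed: int | None = None) -> "IntegrationResults":
        """Train and return results with the fused-mean embedding.

        With ``epochs=0`` returns the freshly initialized model's embedding
        and an empty history.
        """
        cfg = self.config
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        ds = self.dataset
        N = ds.n_cells
        ss = np.random.SeedSequence(cfg.seed)
        s_init, s_shuf, s_pairs, s_tri, s_rep = ss.spawn(5)
        rng_shuf = np.random.default_rng(s_shuf)
        rng_pairs = np.random.default_rng(s_pairs)
        rng_tri = np.random.default_rng(s_tri)
        rng_rep = np.random.default_rng(s_rep)

        n_features = {m: self.pre.views[m].shape[1] for m in ds.modalities}
        params = ModelParams.build(
            n_features,
            latent_dim=cfg.latent_dim,
            hidden=cfg.hidden,
            seed=int(np.random.default_rng(s_init).integers(2**31)),
        )
        graph = self._build_graphs()
        opt = Adam(params.parameters, lr=cfg.learning_rate)

        weights = cfg.weights
        n_classes = len(ds.label_set()) if ds.labels is not None else 0
        if weights.triplet > 0 and n_classes < 2:
            warnings.warn(
                "fewer than 2 labeled classes: triplet loss disabled (weight -> 0)"
            )
            weights = replace(weights, triplet=0.0)

        history: list[LossReport] = []
        B_cfg = min(cfg.batch_size, N)
        for epoch in range(cfg.epochs):
            order = rng_shuf.permutation(N)
            ep = np.zeros(6)
            n_batches = 0
            for start in range(0, N, B_cfg):
                batch_idx = order[start : start + B_cfg]
                B = batch_idx.size
                if B < 2:
                    continue
                post, z, xs, xhats, _ = self._forward_batch(params, batch_idx, rng_rep)

                # normalize recon to a per-cell, per-feature mean and KL to a
                # per-cell mean so the five terms share a scale and the
                # default weights are meaningful across feature dimensions
                d_total = sum(x.shape[1] for x in xs.values())
                l_recon = recon_loss(xs, xhats) * (1.0 / (B * d_total))
                l_kl = kl_loss(post) * (1.0 / B)

                induced = {
                    m: graph.adjacency[m][np.ix_(batch_idx, batch_idx)]
                    for m in ds.modalities
                }
                # N/B^2 scaling makes the induced-subgraph sum an unbiased
                # estimate of the full-graph 1/N cross-entropy
                l_graph = graph_loss(z, induced, n_total=B * B / N)

                pair_set, tri_set = self._batch_supervision(
                    batch_idx, induced, rng_pairs, rng_tri, weights.triplet > 0
                )
                l_con = info_nce_loss(z, pair_set) if pair_set else Tensor(0.0)
                l_tri = (
                    triplet_loss(z, tri_set)
                    if (tri_set is not None and weights.triplet > 0)
                    else Tensor(0.0)
                )

                loss = total_loss(l_recon, l_kl, l_graph, l_con, l_tri, weights)
                if not np.isfinite(loss.value):
                    parts = {
                        "recon": l_recon.item(),
                        "kl": l_kl.item(),
                        "graph": l_graph.item(),
                        "contrastive": l_con.item(),
                        "triplet": l_tri.item(),
                    }
                    bad = [k for k, v in parts.items() if not np.isfinite(v)]
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: {bad or ['total']}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep += [
                    l_recon.item(),
                    l_kl.item(),
                    l_graph.item(),
                    l_con.item(),
                    l_tri.item(),
                    loss.item(),
                ]
                n_batches += 1
            ep /= max(n_batches, 1)
            history.append(LossReport(*ep))

        embedding = self._embed_with(params)
        return IntegrationResults(
            model=self,
            params=params,
            embedding=embedding,
            history=history,
            config=cfg,
            effective_weights=weights,
        )

    # ------------------------------------------------------------------- embed
    def _embed_with(self, params: ModelParams) -> pd.DataFrame:
        ds = self.dataset
        for m in ds.modalities:
            if m not in params.encoders:
                raise ValueError(f"model has no encoder for modality '{m}' in mask")
        post, _, _, _, _ = self._forward_batch(
            params, np.arange(ds.n_cells), np.random.default_rng(0), sample=False
        )
        return pd.DataFrame(
            post.mean.value,
            index=pd.Index(ds.barcodes, name="barcode"),
            columns=[f"latent_{i}" for i in range(post.mean.shape[1])],
        )


@dataclass
class IntegrationResults:
    """Fitted embedding, loss history and parameters of one training run."""

    model: MosaicIntegrationModel
    params: ModelParams
    embedding: pd.DataFrame
    history: list[LossReport]
    config: TrainConfig
    effective_weights: LossWeights

    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([h.__dict__ for h in self.history])

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            "Mosaic multimodal integration (PoE VAE)",
            "=" * 46,
            f"cells: {ds.n_cells}   modalities: {', '.join(ds.modalities)}",
            f"batches: {len(set(ds.batch))}   latent dim: {self.config.latent_dim}",
            f"epochs: {self.config.epochs}   batch size: {self.config.batch_size}"
            f"   lr: {self.config.learning_rate}",
            f"weights (recon, kl, graph, con, tri): {self.effective_weights.as_tuple()}",
        ]
        if self.history:
            first, last = self.history[0], self.history[-1]
            lines += [
                "-" * 46,
                f"{'term':<14}{'epoch 1':>14}{'final':>14}",
            ]
            for t in ("recon", "kl", "graph", "contrastive", "triplet", "total"):
                lines.append(
                    f"{t:<14}{getattr(first, t):>14.4f}{getattr(last, t):>14.4f}"
                )
        return "\n".join(lines)

    def evaluate(self, labels=None, resolution: float = 1.0,
                 k_neighbors: int = 15, seed: int = 0):
        """Cluster the embedding and score it against cell-type labels.

        `labels` defaults to the training dataset's label vector; pass the
        full ground-truth vector when the model was trained on a
        semi-supervised (partially masked) copy.
        """
        from .evaluate import evaluate_embedding

        ds = self.model.dataset
        if labels is None:
            labels = ds.labels
        if labels is None:
            raise ValueError("dataset has no labels to evaluate against")
        return evaluate_embedding(
            self.embedding.to_numpy(),
            np.asarray(labels, dtype=object),
            ds.batch,
            resolution=resolution,
            k_neighbors=k_neighbors,
            seed=seed,
        )

    def save_embedding(self, path: str | Path) -> None:
        self.embedding.to_csv(path, sep="\t")

    def save_history(self, path: str | Path) -> None:
        self.history_frame.to_csv(path, index=False)

    def save_checkpoint(self, path: str | Path) -> None:
        """Single zip archive: JSON architecture manifest + parameter arrays."""
        manifest = {
            "modalities": list(self.params.encoders),
            "n_features": {
                m: self.model.pre.views[m].shape[1] for m in self.params.encoders
            },
            "latent_dim": self.params.latent_dim,
            "hidden": self.params.hidden,
            "config": json.loads(self.config.to_json()),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("manifest.json", json.dumps(manifest, indent=2))
            for name, arr in self.params.state_arrays().items():
                buf = BytesIO()
                np.save(buf, arr)
                zf.writestr(name.replace("/", "__") + ".npy", buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[ModelParams, dict]:
    """Load parameters and the architecture manifest from a checkpoint."""
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        params = ModelParams.build(
            {m: int(p) for m, p in manifest["n_features"].items()},
            latent_dim=manifest["latent_dim"],
            hidden=manifest["hidden"],
        )
        state = {}
        for name in zf.namelist():
            if name.endswith(".npy"):
                key = name[: -len(".npy")].replace("__", "/")
                state[key] = np.load(BytesIO(zf.read(name)))
        params.load_state_arrays(state)
    return params, manifest


def embed(ds: MosaicDataset, params: ModelParams,
          pre: PreprocessedDataset | None = None) -> pd.DataFrame:
    """Deterministic fused posterior-mean embedding for a dataset."""
    model = MosaicIntegrationModel(ds, preprocessed=pre)
    return model._embed_with(params)
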