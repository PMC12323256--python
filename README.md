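# mosaicvae

Integration of **mosaic single-cell multimodal data** — multi-batch
collections in which different batches carry different subsets of modalities
(RNA transcript counts, ATAC chromatin accessibility, ADT surface-protein
tags) — into one batch-corrected latent embedding.

The package is for computational biologists who need to co-embed, say, a
10x Multiome batch (RNA+ATAC) with a CITE-seq batch (RNA+ADT) without
requiring any batch to carry all modalities, and who want cluster-ready
latent coordinates plus the standard integration scorecard (NMI, ARI, graph
connectivity, iLISI, cLISI).

## The model

Each modality $m$ has its own encoder producing a diagonal-Gaussian
posterior $q_\phi(z \mid x_n^m) = \mathcal N(\mu_n^m, \mathrm{diag}(\nu_n^m))$
over a shared latent space. For cell $n$ with available modalities
$\mathcal M_n$, the posteriors are fused by a **product of experts**
together with the standard-normal prior:

$$
\nu_n = \Big(1 + \sum_{m \in \mathcal M_n} 1/\nu_n^m\Big)^{-1}, \qquad
\mu_n = \Big(\sum_{m \in \mathcal M_n} \mu_n^m / \nu_n^m\Big) \circ \nu_n .
$$

Precisions add, so cells are embeddable from any non-empty subset of
modalities — the essence of mosaic integration. Per-modality decoders
reconstruct each view from a reparameterized sample $z_n$, and training
minimizes

$$
\mathcal L = \lambda_1 \mathcal L_{recon} + \lambda_2 \mathcal L_{KL}
 + \lambda_3 \mathcal L_{graph} + \lambda_4 \mathcal L_{con}
 + \lambda_5 \mathcal L_{tri},
$$

with (i) MSE reconstruction, (ii) the closed-form KL of the fused posterior
from $\mathcal N(0, I)$, (iii) a graph cross-entropy tying
$\mathrm{sigmoid}(z_i^\top z_j)$ to each modality's cosine **mutual-KNN
adjacency** so the latent space preserves each modality's neighborhood
topology, (iv) a symmetrized **InfoNCE** contrastive term over positive
pairs sampled from those adjacency edges, and (v) a **triplet hinge**
$\max(d(a,p) - d(a,n) + m, 0)$ over partially labeled cells
(semi-supervision). The graph and contrastive terms carry cross-batch
neighbor relations of the bridging modality, and the triplet term uses
sparse labels across batches; together they remove batch effects while the
VAE terms preserve biology.

Everything runs on a small numpy reverse-mode autodiff engine shipped with
the package (CPU, float64, bitwise deterministic for a fixed seed).

## Worked example

```python
from mosaicvae import (MosaicIntegrationModel, SimulationConfig,
                       make_semisupervised, simulate_mosaic)

# 600 cells, 4 types, 2 batches: batch0 = RNA+ATAC, batch1 = RNA+ADT
cfg = SimulationConfig(n_cells=600, n_types=4, n_batches=2,
                       batch_effect_scale=1.0, seed=0)
truth, _ = simulate_mosaic(cfg)
dataset = make_semisupervised(truth, fraction=0.2, seed=1000)  # 20% labels

model = MosaicIntegrationModel.from_dataset(dataset, epochs=200, seed=0)
results = model.fit()
print(results.summary())
report = results.evaluate(labels=truth.labels)
```

`results.summary()` prints the loss table:

```
Mosaic multimodal integration (PoE VAE)
==============================================
cells: 600   modalities: rna, atac, adt
batches: 2   latent dim: 20
epochs: 200   batch size: 128   lr: 0.001
weights (recon, kl, graph, con, tri): (1.0, 0.1, 1.0, 1.0, 1.0)
----------------------------------------------
term                 epoch 1         final
recon                 8.1424        1.2617
kl                   72.1403       11.7622
graph                 3.2727        0.0026
contrastive          13.0414       11.5998
triplet               0.8385        0.0044
total                32.5089       14.0447
```

and the scorecard comes out as

```
{"nmi": 1.0, "ari": 1.0, "graph_connectivity": 1.0,
 "ilisi": 0.471, "clisi": 1.0, "n_clusters": 4}
```

ARI/NMI of 1.0 mean Leiden clusters on the embedding coincide exactly with
the simulated cell types; iLISI 0.47 means a typical latent neighborhood
mixes the two batches (a concatenate-and-PCA baseline scores ≈ 0.00 here);
cLISI 1.0 means neighborhoods are pure in cell type.

The same pipeline is scriptable from the shell:

```bash
mosaicvae simulate --out data/ --label-fraction 0.2
mosaicvae train --data data/manifest.json --out run/
mosaicvae embed --checkpoint run/checkpoint.zip --data data/manifest.json --out emb.tsv
mosaicvae evaluate --embedding run/embedding.tsv --labels labels.tsv \
    --batches batches.tsv --out report.json
```

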