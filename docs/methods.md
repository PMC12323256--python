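# Methods

## Model

`mosaicvae` fits a modular variational autoencoder to mosaic multimodal
single-cell data. Observed counts per modality are normalized
(total-count + log1p for RNA and ADT, TF-IDF for ATAC; CLR is available for
ADT) and each modality's view is encoded by its own two-layer MLP
(default 128 hidden units, ReLU) into a diagonal-Gaussian posterior over a
shared 20-dimensional latent space. The variance head uses a softplus link
with a floor of 1e-6 so posterior precisions are always finite.

For each cell the posteriors of its available modalities are fused as a
product of experts including the standard-normal prior: fused precision is
one plus the sum of expert precisions, fused mean the precision-weighted
average. A cell missing a modality simply contributes no expert for it —
no imputation, no zero-filling enters the encoder. The fused distribution is
sampled via the reparameterization trick and decoded per modality by
two-layer MLPs; reconstruction error is mean squared error on the
normalized views (not a count likelihood — the model trades likelihood
calibration for robustness across heterogeneous modality scales).

Five loss terms are combined with weights λ = (1, 0.1, 1, 1, 1):

1. **Reconstruction** — squared error over available (cell, modality)
   pairs. The printed objective is a sum over cells; inside the trainer it
   is normalized to a per-cell, per-feature mean so its scale does not grow
   with feature count. Without this the ~600-feature reconstruction term is
   five to six orders of magnitude larger than every other term, and no
   reasonable weight assignment recovers balance (Adam's per-parameter
   normalization cannot correct a dominant shared gradient direction).
2. **KL** — closed-form divergence of the fused posterior from N(0, I),
   per-cell mean in the trainer. The default weight 0.1 on this mean is the
   term that keeps the latent scale compact enough for the geometric losses
   to act; with a much smaller weight the embedding inflates and types
   split by batch.
3. **Graph cross-entropy** — per modality, a cosine mutual-KNN graph
   (default k = 15, built once on the normalized views over the cells where
   the modality is available; top-k ties break toward the lower cell index
   for determinism). The loss is −(1/N) Σ over adjacency entries of
   log sigmoid(z_i·z_j), computed with a numerically stable log-sigmoid.
   On a mini-batch the induced subgraph is used with an N/B² scale factor:
   an edge survives batch subsetting with probability ≈ (B/N)², so this
   makes the batch estimate unbiased for the full-data form and reduces to
   it exactly at full batch.
4. **InfoNCE** — positive pairs are edges of the per-modality graphs;
   the loss is the symmetrized form with temperature τ = 0.5, where the
   denominator for a pair includes all other sampled positives (and, in its
   second sum, the pair's own score). Pairs are resampled every mini-batch
   from the in-batch induced edges (default T = 100 per modality) so both
   members always have in-batch embeddings; this is the per-epoch
   resampling default taken to finer granularity.
5. **Triplet hinge** — for partially labeled data, H = 100 triples per
   mini-batch (anchor and positive share a label, negative differs;
   anchors only from classes with ≥ 2 labeled cells in the batch), margin
   1.0, Euclidean distance. The hinge mean is **minimized with positive
   sign**; a negated hinge would reward unbounded distances and contradict
   the goal of pulling same-type cells together. If fewer than two labeled
   classes exist the term is disabled with a warning. Triplets are sampled
   globally with respect to batch: cross-batch same-type positives are
   exactly what drives batch alignment.

Optimization is Adam (lr 1e-3, batch 128, default 200 epochs) in float64
numpy with a purpose-built reverse-mode autodiff engine
(`mosaicvae._autograd`); gradients are test-verified against central finite
differences. Single-threaded execution makes runs bitwise reproducible for
a fixed seed: initialization, shuffling, pair/triplet sampling and
reparameterization noise each use an independent child stream of one seed.
The reported embedding is the fused posterior **mean** (no sampling), the
standard convention for downstream clustering.

## Synthetic data generator

The generator emulates the structure the method targets, not any real
dataset's count distributions. Cell types are Gaussian clusters
(centroid sd 2.0, within-type noise sd 0.3) in a 10-dimensional latent
space; each batch adds a shared latent offset plus a small (0.2×)
per-modality offset. `batch_effect_scale` is expressed in units of the
within-type noise sd: scale 1.0 shifts each batch by about one noise sd per
coordinate — a clearly visible effect (a concatenated-PCA embedding
separates batches almost completely) that still leaves cross-batch
mutual-KNN neighbors for shared cell types (~30% of RNA edges at defaults),
i.e. the removable-batch-effect regime a shared-latent method is designed
for. Each modality observes the latent through a fixed random linear map
with exponential link; RNA and ADT counts are negative binomial
(gamma–Poisson, dispersions 2 and 4), ATAC is Bernoulli-thinned Poisson to
mimic near-binary sparsity. The default mosaic pattern gives batch 0
RNA+ATAC and batch 1 RNA+ADT, with RNA as the bridging modality.

What passing tests on this generator do show: the architecture can fuse
disjoint modality sets through the shared latent, remove a latent-shift
batch effect, and exploit sparse labels. What they do not show: robustness
to real-data properties the generator omits — nonlinear batch distortions,
imbalanced and batch-specific cell types, ambient contamination, doublets,
depth gradients, or realistic ATAC dimensionality (hundreds of features
here, hundreds of thousands in practice).

## Evaluation

Leiden clustering (RBConfiguration, resolution 1.0, seeded) on an exact
Euclidean KNN graph (k = 15) of the embedding. NMI uses arithmetic-mean
entropy normalization; ARI is reported raw. Graph connectivity is the mean
over label classes of the largest-connected-component fraction of the
class-induced KNN subgraph. iLISI/cLISI are graph-based local inverse
Simpson indices with a per-cell Gaussian kernel calibrated to perplexity 30
over the 90 nearest neighbors, rescaled to [0,1]: iLISI as
(score − 1)/(B − 1) (1 = perfectly mixed batches), cLISI as
(C − score)/(C − 1) (1 = perfectly pure types). The batch-mixing baseline
concatenates all normalized views (zeros where a modality is missing) and
projects with PCA to the same dimensionality as the model's latent space.

## Numerical and design notes

- All-zero cells within an available modality are left as zero rows with a
  warning; graph construction rejects them (cosine undefined), so upstream
  filtering is the caller's responsibility.
- Mutual-KNN makes adjacency symmetric by construction and strictly a
  subgraph of the directed KNN relation; k = 0 yields an empty graph.
- InfoNCE requires at least two pairs per modality (the denominator's
  first sum is otherwise empty); modalities whose graphs have no edges are
  skipped with a warning.
- The contrastive/graph/triplet terms operate on the latent *sample* during
  training (gradients flow through the reparameterization), but evaluation
  always uses posterior means.
- Problem sizes in the test and acceptance workloads (600 cells, ~630
  features across three modalities, 200 epochs, three seeds) were chosen as
  the smallest regime in which type recovery, batch mixing and the
  semi-supervision effect are all cleanly measurable.

## Known limitations

- MSE reconstruction on normalized views ignores count overdispersion; no
  NB/ZINB decoder is provided by design.
- Exact brute-force KNN and dense Gram-matrix losses are O(N²); the
  implementation targets desk-scale datasets (thousands of cells), not
  atlases.
- The triplet term can only enforce relative geometry; with very separated
  types its hinge saturates early and most batch alignment is carried by
  the KL/graph/contrastive terms.
- No early stopping, hyperparameter search, GPU support, or feature
  selection (HVG)/QC filtering.
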