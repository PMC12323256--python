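"""Synthetic mosaic multimodal datasets with known ground truth.

The generative story mirrors the regime a shared-latent integration method
targets: cells of each type sit around a centroid in a low-dimensional
biological latent space; batches shift that latent by an offset vector
(shared across modalities) plus a small per-modality offset; each modality
observes the latent through a fixed random linear map; RNA and ADT counts are
negative binomial, ATAC counts are Bernoulli-thinned Poisson to mimic the
near-binary sparsity of accessibility data. The batch x modality mosaic
pattern decides which modalities each batch carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MISSING_LABEL, MosaicDataset


def _default_features() -> dict[str, int]:
    return {"rna": 200, "atac": 400, "adt": 30}


@dataclass
class SimulationConfig:
    """Parameters of the mosaic simulation.

    ``mosaic_pattern`` maps batch index -> tuple of available modalities; the
    default gives batch 0 RNA+ATAC and batch 1 RNA+ADT, the canonical mosaic
    regime where RNA is the bridging modality. ``batch_effect_scale`` is the
    per-batch latent offset in units of the within-type noise sd
    (``noise_scale``): scale 1.0 shifts each batch by about one noise sd per
    latent coordinate — a clearly visible batch effect that still leaves
    cross-batch neighbors for shared types, i.e. the removable regime a
    shared-latent method targets.
    """

    n_cells: int = 600
    n_types: int = 4
    n_batches: int = 2
    latent_dim_true: int = 10
    n_features: dict[str, int] = field(default_factory=_default_features)
    batch_effect_scale: float = 1.0
    noise_scale: float = 0.3
    centroid_scale: float = 2.0
    nb_dispersion: dict[str, float] = field(default_factory=lambda: {"rna": 2.0, "adt": 4.0})
    atac_rate: float = 0.5
    mosaic_pattern: dict[int, tuple[str, ...]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if self.batch_effect_scale < 0 or self.noise_scale < 0:
            raise ValueError("scales must be non-negative")
        if self.mosaic_pattern is None:
            self.mosaic_pattern = _default_pattern(self.n_batches, list(self.n_features))
        for b in range(self.n_batches):
            mods = self.mosaic_pattern.get(b, ())
            if not mods:
                raise ValueError(f"batch {b} has an empty modality set")
            for m in mods:
                if m not in self.n_features:
                    raise ValueError(f"unknown modality '{m}' in mosaic_pattern")


def _default_pattern(n_batches: int, modalities: list[str]) -> dict[int, tuple[str, ...]]:
    if n_batches == 1:
        return {0: tuple(modalities)}
    pattern = {}
    non_rna = [m for m in modalities if m != "rna"] or modalities
    for b in range(n_batches):
        other = non_rna[b % len(non_rna)]
        pattern[b] = ("rna", other) if "rna" in modalities else (other,)
    return pattern


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB as gamma-Poisson; dispersion r: var = mu + mu^2/r
    shape = dispersion
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam).astype(np.float64)


def simulate_mosaic(config: SimulationConfig) -> tuple[MosaicDataset, np.ndarray]:
    """Draw a mosaic dataset; returns (dataset, true latent matrix).

    The returned dataset carries the ground-truth type label for every cell;
    use :func:`make_semisupervised` to hide a fraction of them.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_cells, config.latent_dim_true

    types = rng.integers(config.n_types, size=n)
    batches = rng.integers(config.n_batches, size=n)
    centroids = rng.normal(0.0, config.centroid_scale, size=(config.n_types, d))
    latent = centroids[types] + rng.normal(0.0, config.noise_scale, size=(n, d))

    offset_sd = config.batch_effect_scale * config.noise_scale
    batch_offsets = rng.normal(0.0, offset_sd, size=(config.n_batches, d))
    latent_obs = latent + batch_offsets[batches]

    modalities = list(config.n_features)
    counts: dict[str, np.ndarray] = {}
    feature_names: dict[str, list[str]] = {}
    mask = np.zeros((n, len(modalities)), dtype=bool)
    for j, m in enumerate(modalities):
        p = config.n_features[m]
        loading = rng.normal(0.0, 1.0, size=(d, p)) / np.sqrt(d)
        # small per-modality batch offset on top of the shared latent shift
        mod_offsets = rng.normal(
            0.0, 0.2 * offset_sd, size=(config.n_batches, p)
        )
        act = latent_obs @ loading + mod_offsets[batches]
        mean = np.exp(np.clip(act, -8, 8))
        if m == "atac":
            lam = config.atac_rate * mean / mean.mean()
            raw = rng.poisson(np.clip(lam, 0, 50)).astype(np.float64)
            keep = rng.random(raw.shape) < 0.7
            x = raw * keep
        else:
            scale = {"rna": 5.0, "adt": 20.0}.get(m, 5.0)
            mu = scale * mean / mean.mean()
            x = _nb_counts(rng, np.clip(mu, 1e-8, 1e4), config.nb_dispersion.get(m, 2.0))
        counts[m] = x
        feature_names[m] = [f"{m}_f{i}" for i in range(p)]
        for b, mods in config.mosaic_pattern.items():
            if m in mods:
                mask[batches == b, j] = True

    # zero out counts for unavailable cells so the container stays tidy
    for j, m in enumerate(modalities):
        counts[m][~mask[:, j]] = 0.0

    ds = MosaicDataset(
        counts=counts,
        mask=mask,
        batch=np.array([f"batch{b}" for b in batches], dtype=object),
        barcodes=[f"cell{i:05d}" for i in range(n)],
        feature_names=feature_names,
        labels=np.array([f"type{t}" for t in types], dtype=object),
    )
    return ds, latent


def make_semisupervised(ds: MosaicDataset, fraction: float, seed: int = 0) -> MosaicDataset:
    """Keep labels for a stratified `fraction` of cells, mask the rest.

    Stratified by type so every type retains at least one label whenever
    fraction > 0; with fraction = 0 all labels are masked.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if ds.labels is None:
        raise ValueError("dataset has no labels to subsample")
    rng = np.random.default_rng(seed)
    new = np.array([MISSING_LABEL] * ds.n_cells, dtype=object)
    if fraction > 0:
        for t in ds.label_set():
            idx = np.where(ds.labels == t)[0]
            n_keep = max(1, int(round(fraction * idx.size)))
            keep = rng.choice(idx, size=min(n_keep, idx.size), replace=False)
            new[keep] = t
    return MosaicDataset(
        counts={m: ds.counts[m].copy() for m in ds.modalities},
        mask=ds.mask.copy(),
        batch=ds.batch.copy(),
        barcodes=list(ds.barcodes),
        feature_names={m: list(v) for m, v in ds.feature_names.items()},
        labels=new,
    )
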