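import numpy as np
import pytest

from mosaicvae import (
    MosaicIntegrationModel,
    SimulationConfig,
    make_semisupervised,
    simulate_mosaic,
)


@pytest.fixture(scope="session")
def small_sim():
    """Small mosaic dataset: 150 cells, 3 types, 2 batches (RNA bridge)."""
    cfg = SimulationConfig(
        n_cells=150,
        n_types=3,
        n_batches=2,
        n_features={"rna": 60, "atac": 80, "adt": 12},
        seed=42,
    )
    ds, latent = simulate_mosaic(cfg)
    return ds, latent


@pytest.fixture(scope="session")
def quick_fit(small_sim):
    """A short training run shared across tests that only need *a* result."""
    ds, _ = small_sim
    ds2 = make_semisupervised(ds, 0.3, seed=7)
    model = MosaicIntegrationModel.from_dataset(
        ds2, epochs=8, batch_size=64, k=10, T=30, H=30, seed=11
    )
    return model, model.fit()


def rng(seed=0):
    return np.random.default_rng(seed)
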