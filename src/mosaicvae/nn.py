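"""Modular VAE building blocks: per-modality Gaussian encoders, product-of-
experts fusion, reparameterized sampling, per-modality decoders, and Adam.

Each modality has its own encoder mapping its normalized view to a diagonal
Gaussian posterior over a shared latent space, and its own decoder mapping a
latent sample back to the view. Posteriors for a cell's available modalities
are fused by multiplying densities together with the standard-normal prior
(product of experts): precisions add, means combine precision-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, as_tensor

VARIANCE_FLOOR = 1e-6  # protects 1/nu in the PoE fusion


@dataclass
class GaussianPosterior:
    """Diagonal Gaussian over the latent space, one row per cell."""

    mean: Tensor
    variance: Tensor

    def __post_init__(self):
        self.mean = as_tensor(self.mean)
        self.variance = as_tensor(self.variance)
        v = self.variance.value
        if not np.all(np.isfinite(v)) or (v.size and v.min() <= 0):
            raise ValueError("posterior variance must be strictly positive and finite")

    @property
    def n_cells(self) -> int:
        return self.mean.shape[0]


def _he_init(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))


class MLP:
    """Fully connected net with ReLU hidden layers; linear output."""

    def __init__(self, sizes: list[int], rng: np.random.Generator):
        self.sizes = list(sizes)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            self.weights.append(Tensor(_he_init(rng, a, b), requires_grad=True))
            self.biases.append(Tensor(np.zeros(b), requires_grad=True))

    def __call__(self, x: Tensor) -> Tensor:
        h = as_tensor(x)
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i != last:
                h = h.relu()
        return h

    @property
    def parameters(self) -> list[Tensor]:
        return self.weights + self.biases


class Encoder:
    """Maps a modality view to per-cell posterior mean and variance.

    The variance head uses a softplus link plus a small floor so the
    product-of-experts precision 1/nu is always finite.
    """

    def __init__(self, n_features: int, hidden: list[int], latent_dim: int,
                 rng: np.random.Generator):
        self.latent_dim = latent_dim
        self.net = MLP([n_features] + hidden + [2 * latent_dim], rng)

    def __call__(self, x: Tensor) -> GaussianPosterior:
        x = as_tensor(x)
        if not np.all(np.isfinite(x.value)):
            raise ValueError("encoder input contains non-finite values")
        out = self.net(x)
        d = self.latent_dim
        mean = _slice_cols(out, 0, d)
        raw = _slice_cols(out, d, 2 * d)
        variance = raw.softplus() + VARIANCE_FLOOR
        return GaussianPosterior(mean=mean, variance=variance)

    @property
    def parameters(self) -> list[Tensor]:
        return self.net.parameters


def _slice_cols(t: Tensor, start: int, stop: int) -> Tensor:
    """Column slice as an autograd op (via transpose + row gather)."""
    return t.T.gather_rows(np.arange(start, stop)).T


class Decoder:
    """Maps latent samples back to one modality's feature space."""

    def __init__(self, latent_dim: int, hidden: list[int], n_features: int,
                 rng: np.random.Generator):
        self.net = MLP([latent_dim] + hidden + [n_features], rng)

    def __call__(self, z: Tensor) -> Tensor:
        z = as_tensor(z)
        if not np.all(np.isfinite(z.value)):
            raise ValueError("decoder input contains non-finite values")
        return self.net(z)

    @property
    def parameters(self) -> list[Tensor]:
        return self.net.parameters


@dataclass
class ModelParams:
    """One encoder and one decoder per modality plus architecture metadata."""

    encoders: dict[str, Encoder]
    decoders: dict[str, Decoder]
    latent_dim: int
    hidden: list[int] = field(default_factory=lambda: [128])

    @property
    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for e in self.encoders.values():
            ps.extend(e.parameters)
        for d in self.decoders.values():
            ps.extend(d.parameters)
        return ps

    @staticmethod
    def build(n_features: dict[str, int], latent_dim: int = 20,
              hidden: list[int] | None = None, seed: int = 0) -> "ModelParams":
        hidden = list(hidden) if hidden is not None else [128]
        rng = np.random.default_rng(seed)
        encoders = {m: Encoder(p, hidden, latent_dim, rng) for m, p in n_features.items()}
        decoders = {m: Decoder(latent_dim, hidden, p, rng) for m, p in n_features.items()}
        return ModelParams(encoders=encoders, decoders=decoders,
                           latent_dim=latent_dim, hidden=hidden)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for m, e in self.encoders.items():
            for i, p in enumerate(e.parameters):
                out[f"enc/{m}/{i}"] = p.value
        for m, d in self.decoders.items():
            for i, p in enumerate(d.parameters):
                out[f"dec/{m}/{i}"] = p.value
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for m, e in self.encoders.items():
            for i, p in enumerate(e.parameters):
                p.value = np.asarray(state[f"enc/{m}/{i}"], dtype=np.float64)
        for m, d in self.decoders.items():
            for i, p in enumerate(d.parameters):
                p.value = np.asarray(state[f"dec/{m}/{i}"], dtype=np.float64)


def poe_combine(
    experts: dict[str, GaussianPosterior],
    expert_cells: dict[str, np.ndarray],
    n_cells: int,
) -> GaussianPosterior:
    """Product-of-experts fusion with the standard-normal prior expert.

    Fused variance  nu = (1 + sum_m 1/nu^m)^{-1}  elementwise; fused mean
    mu = (sum_m mu^m / nu^m) * nu. The leading 1 is the unit-variance prior,
    so a cell with no experts gets the prior (mu=0, nu=1) — guarded upstream
    by the mask invariant. `expert_cells[m]` gives the row index each expert
    posterior row refers to.
    """
    if not experts:
        d = 1
        return GaussianPosterior(mean=Tensor(np.zeros((n_cells, d))),
                                 variance=Tensor(np.ones((n_cells, d))))
    d = next(iter(experts.values())).mean.shape[1]
    prec_sum: Tensor | None = None
    mean_prec_sum: Tensor | None = None
    for m, post in experts.items():
        idx = expert_cells[m]
        prec = 1.0 / post.variance
        mp = post.mean * prec
        prec_full = prec.scatter_rows(idx, n_cells)
        mp_full = mp.scatter_rows(idx, n_cells)
        prec_sum = prec_full if prec_sum is None else prec_sum + prec_full
        mean_prec_sum = mp_full if mean_prec_sum is None else mean_prec_sum + mp_full
    fused_var = 1.0 / (1.0 + prec_sum)
    fused_mean = mean_prec_sum * fused_var
    return GaussianPosterior(mean=fused_mean, variance=fused_var)


def poe_combine_single(means: list, variances: list) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form PoE for one cell given expert mean/variance arrays.

    Convenience numpy form of :func:`poe_combine`; accepts any number of
    experts including none (returns the prior).
    """
    means = [np.asarray(m, dtype=np.float64) for m in means]
    variances = [np.asarray(v, dtype=np.float64) for v in variances]
    for v in variances:
        if np.any(v <= 0):
            raise ValueError("expert variances must be strictly positive")
    shape = means[0].shape if means else (1,)
    prec = np.ones(shape)
    mp = np.zeros(shape)
    for m, v in zip(means, variances):
        prec = prec + 1.0 / v
        mp = mp + m / v
    nu = 1.0 / prec
    return mp * nu, nu


def reparameterize(post: GaussianPosterior, rng: np.random.Generator) -> Tensor:
    """Sample z = mu + sqrt(nu) * eps with eps from the seeded stream."""
    eps = rng.standard_normal(post.mean.shape)
    return post.mean + post.variance.sqrt() * Tensor(eps)


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
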