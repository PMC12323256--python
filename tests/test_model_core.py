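"""Encoders, product-of-experts fusion, reparameterization, decoders.

The PoE closed form is checked against a 1-D grid-integration oracle: the
pointwise product of the expert densities and the standard-normal prior,
renormalized, must have the same mean and variance.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicvae import GaussianPosterior, ModelParams, poe_combine, poe_combine_single, reparameterize
from mosaicvae._autograd import Tensor


def grid_poe_oracle(means, variances, lo=-15.0, hi=15.0, n=60001):
    """Numerically integrate the renormalized product of expert densities
    (including the standard-normal prior)."""
    x = np.linspace(lo, hi, n)
    log_dens = -0.5 * x**2  # prior, unnormalized
    for m, v in zip(means, variances):
        log_dens = log_dens - 0.5 * (x - m) ** 2 / v
    dens = np.exp(log_dens - log_dens.max())
    z = np.trapezoid(dens, x)
    p = dens / z
    mean = np.trapezoid(x * p, x)
    var = np.trapezoid((x - mean) ** 2 * p, x)
    return mean, var


class TestPoE:
    @pytest.mark.parametrize(
        "means,variances,exp_mean,exp_var",
        [
            ([0.0], [1.0], 0.0, 0.5),
            ([2.0], [1.0], 1.0, 0.5),
            ([], [], 0.0, 1.0),  # prior when no experts
        ],
    )
    def test_forced_closed_form_values(self, means, variances, exp_mean, exp_var):
        mu, nu = poe_combine_single(means, variances)
        np.testing.assert_allclose(mu, exp_mean)
        np.testing.assert_allclose(nu, exp_var)

    def test_two_equal_variance_experts(self):
        mu, nu = poe_combine_single([1.0, 3.0], [1.0, 1.0])
        np.testing.assert_allclose(nu, 1 / 3)
        np.testing.assert_allclose(mu, 4 / 3)
        om, ov = grid_poe_oracle([1.0, 3.0], [1.0, 1.0])
        np.testing.assert_allclose(mu, om, atol=1e-6)
        np.testing.assert_allclose(nu, ov, atol=1e-6)

    def test_grid_oracle_equivalence_random_expert_sets(self):
        """50 random 1-D expert sets match the density-product oracle."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n_exp = rng.integers(1, 4)
            means = rng.uniform(-3, 3, n_exp)
            variances = rng.uniform(0.1, 4, n_exp)
            mu, nu = poe_combine_single(means, variances)
            om, ov = grid_poe_oracle(means, variances)
            np.testing.assert_allclose(mu, om, atol=1e-6)
            np.testing.assert_allclose(nu, ov, atol=1e-6)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            poe_combine_single([0.0], [-1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.floats(-5, 5), st.floats(0.05, 10)), min_size=0, max_size=4
        )
    )
    def test_fusion_invariants(self, experts):
        means = [m for m, _ in experts]
        variances = [v for _, v in experts]
        mu, nu = poe_combine_single(means, variances)
        # precisions add: fused variance below every expert's and the prior's
        assert np.all(nu <= 1.0 + 1e-12)
        for v in variances:
            assert np.all(nu <= v + 1e-12)
        # fused mean in the convex hull of {0} + expert means
        lo = min([0.0] + means)
        hi = max([0.0] + means)
        assert lo - 1e-9 <= mu <= hi + 1e-9

    def test_batched_poe_matches_single_cell_form(self):
        rng = np.random.default_rng(1)
        n, d = 6, 3
        mu_a = rng.normal(size=(4, d))
        nu_a = rng.uniform(0.2, 2, size=(4, d))
        mu_b = rng.normal(size=(5, d))
        nu_b = rng.uniform(0.2, 2, size=(5, d))
        cells_a = np.array([0, 1, 2, 4])
        cells_b = np.array([0, 2, 3, 4, 5])
        fused = poe_combine(
            {
                "a": GaussianPosterior(Tensor(mu_a), Tensor(nu_a)),
                "b": GaussianPosterior(Tensor(mu_b), Tensor(nu_b)),
            },
            {"a": cells_a, "b": cells_b},
            n,
        )
        for cell in range(n):
            means, variances = [], []
            if cell in cells_a:
                i = list(cells_a).index(cell)
                means.append(mu_a[i])
                variances.append(nu_a[i])
            if cell in cells_b:
                i = list(cells_b).index(cell)
                means.append(mu_b[i])
                variances.append(nu_b[i])
            mu, nu = poe_combine_single(means, variances)
            np.testing.assert_allclose(fused.mean.value[cell], mu, atol=1e-12)
            np.testing.assert_allclose(fused.variance.value[cell], nu, atol=1e-12)


class TestEncoderDecoder:
    def test_encoder_variance_positive_and_deterministic(self):
        params = ModelParams.build({"rna": 20}, latent_dim=5, seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 20))
        x[1] = x[0]
        post = params.encoders["rna"](Tensor(x))
        assert np.all(post.variance.value > 0)
        np.testing.assert_array_equal(post.mean.value[0], post.mean.value[1])

    def test_fresh_networks_finite_on_zero_input(self):
        params = ModelParams.build({"rna": 7}, latent_dim=3, seed=1)
        post = params.encoders["rna"](Tensor(np.zeros((2, 7))))
        assert np.all(np.isfinite(post.mean.value))
        assert np.all(np.isfinite(post.variance.value))
        out = params.decoders["rna"](Tensor(np.zeros((2, 3))))
        assert out.shape == (2, 7)
        assert np.all(np.isfinite(out.value))

    def test_nonfinite_input_rejected(self):
        params = ModelParams.build({"rna": 4}, latent_dim=2, seed=2)
        bad = np.full((1, 4), np.nan)
        with pytest.raises(ValueError):
            params.encoders["rna"](Tensor(bad))

    def test_identical_latents_decode_identically(self):
        params = ModelParams.build({"adt": 6}, latent_dim=3, seed=3)
        z = np.ones((2, 3))
        out = params.decoders["adt"](Tensor(z))
        np.testing.assert_array_equal(out.value[0], out.value[1])


class TestReparameterize:
    def test_zero_variance_limit_returns_mean(self):
        mu = np.array([[1.0, -2.0]])
        post = GaussianPosterior(Tensor(mu), Tensor(np.full((1, 2), 1e-18)))
        z = reparameterize(post, np.random.default_rng(0))
        np.testing.assert_allclose(z.value, mu, atol=1e-8)

    def test_seeded_determinism(self):
        post = GaussianPosterior(Tensor(np.zeros((3, 2))), Tensor(np.ones((3, 2))))
        a = reparameterize(post, np.random.default_rng(5))
        b = reparameterize(post, np.random.default_rng(5))
        np.testing.assert_array_equal(a.value, b.value)

    def test_sample_statistics(self):
        post = GaussianPosterior(
            Tensor(np.full((20000, 1), 2.0)), Tensor(np.full((20000, 1), 0.25))
        )
        z = reparameterize(post, np.random.default_rng(1)).value
        assert abs(z.mean() - 2.0) < 0.02
        assert abs(z.std() - 0.5) < 0.02
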