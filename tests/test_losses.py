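"""The five objective terms against hand values and independent oracles."""

import numpy as np
import pytest
from scipy import sparse

from mosaicvae import (
    GaussianPosterior,
    LossWeights,
    NeighborGraph,
    PairSet,
    TripletSet,
    graph_loss,
    info_nce_loss,
    kl_loss,
    recon_loss,
    total_loss,
    triplet_loss,
)
from mosaicvae._autograd import Tensor


class TestRecon:
    def test_zero_for_perfect_reconstruction(self):
        x = np.random.default_rng(0).normal(size=(3, 4))
        assert recon_loss(Tensor(x), Tensor(x.copy())).item() == 0.0

    def test_hand_values(self):
        assert recon_loss(Tensor([[1.0, 0.0]]), Tensor([[0.0, 0.0]])).item() == 1.0
        x = Tensor([[1.0, 1.0], [2.0, 0.0]])
        xh = Tensor([[0.0, 0.0], [0.0, 0.0]])
        assert recon_loss(x, xh).item() == 6.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            recon_loss(Tensor(np.ones((2, 2))), Tensor(np.ones((2, 3))))


class TestKL:
    def test_standard_normal_posterior_gives_zero(self):
        p = GaussianPosterior(Tensor(np.zeros((1, 1))), Tensor(np.ones((1, 1))))
        assert kl_loss(p).item() == pytest.approx(0.0)

    def test_unit_mean_shift(self):
        p = GaussianPosterior(Tensor([[1.0]]), Tensor([[1.0]]))
        assert kl_loss(p).item() == pytest.approx(0.5)

    def test_half_variance_matches_monte_carlo(self):
        p = GaussianPosterior(Tensor([[0.0]]), Tensor([[0.5]]))
        closed = kl_loss(p).item()
        assert closed == pytest.approx(0.096574, abs=1e-5)
        rng = np.random.default_rng(0)
        z = rng.normal(0, np.sqrt(0.5), size=10**6)
        log_q = -0.5 * np.log(np.pi) - z**2  # N(0, 0.5) log-density
        log_p = -0.5 * np.log(2 * np.pi) - 0.5 * z**2
        mc = (log_q - log_p).mean()
        assert closed == pytest.approx(mc, abs=1e-2)

    def test_closed_form_matches_monte_carlo_across_posteriors(self):
        rng = np.random.default_rng(1)
        n_draws = 200_000
        for _ in range(20):
            mu = rng.uniform(-2, 2)
            nu = rng.uniform(0.2, 3)
            p = GaussianPosterior(Tensor([[mu]]), Tensor([[nu]]))
            closed = kl_loss(p).item()
            z = rng.normal(mu, np.sqrt(nu), size=n_draws)
            log_q = -0.5 * np.log(2 * np.pi * nu) - 0.5 * (z - mu) ** 2 / nu
            log_p = -0.5 * np.log(2 * np.pi) - 0.5 * z**2
            samples = log_q - log_p
            se = samples.std() / np.sqrt(n_draws)
            assert abs(closed - samples.mean()) < 3 * max(se, 1e-4)


def _graph(n, edges):
    rows = [i for i, j in edges] + [j for i, j in edges]
    cols = [j for i, j in edges] + [i for i, j in edges]
    adj = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return NeighborGraph(adjacency={"rna": adj}, k=1)


class TestGraphLoss:
    def test_empty_graph_is_zero(self):
        g = NeighborGraph(adjacency={"rna": sparse.csr_matrix((4, 4))}, k=1)
        assert graph_loss(Tensor(np.zeros((4, 2))), g).item() == 0.0

    def test_zero_embedding_hand_value(self):
        g = _graph(4, [(0, 1)])
        expected = (2 / 4) * np.log(2)
        assert graph_loss(Tensor(np.zeros((4, 2))), g).item() == pytest.approx(expected)

    def test_monotone_in_edge_inner_product(self):
        g = _graph(3, [(0, 1)])
        vals = []
        for s in (0.5, 1.0, 2.0):
            z = np.zeros((3, 2))
            z[0, 0] = z[1, 0] = np.sqrt(s)
            vals.append(graph_loss(Tensor(z), g).item())
        assert vals[0] > vals[1] > vals[2]

    def test_stable_for_huge_inner_products(self):
        g = _graph(2, [(0, 1)])
        z = np.array([[100.0], [-100.0]])  # inner product -1e4
        val = graph_loss(Tensor(z), g).item()
        assert np.isfinite(val)


def brute_force_info_nce(z, pairs, tau):
    """Literal nested-loop transcription of the symmetrized InfoNCE."""

    def cos(a, b):
        return a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-0 * 0)

    total = 0.0
    for m, pr in pairs.items():
        T = len(pr)
        za = [z[i] for i, _ in pr]
        zb = [z[j] for _, j in pr]

        def ell(xs, ys, i):
            num = np.exp(cos(xs[i], ys[i]) / tau)
            den = sum(np.exp(cos(xs[i], ys[j]) / tau) for j in range(T) if j != i)
            den += sum(np.exp(cos(xs[j], ys[i]) / tau) for j in range(T))
            return np.log(num / den)

        s = sum(ell(za, zb, i) + ell(zb, za, i) for i in range(T))
        total += -(1 / (2 * T)) * s
    return total


class TestInfoNCE:
    def test_infinite_temperature_limit(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(6, 3))
        ps = PairSet(pairs={"rna": np.array([[0, 1], [2, 3]])}, T=2, tau=1e12)
        assert info_nce_loss(Tensor(z), ps).item() == pytest.approx(np.log(3), abs=1e-6)

    @pytest.mark.parametrize("T", [2, 3, 4, 6])
    def test_matches_nested_loop_oracle(self, T):
        rng = np.random.default_rng(T)
        z = rng.normal(size=(2 * T + 2, 5))
        pr = rng.choice(2 * T + 2, size=(T, 2), replace=False)
        ps = PairSet(pairs={"rna": pr, "atac": pr[::-1].copy()}, T=T, tau=0.5)
        mine = info_nce_loss(Tensor(z), ps).item()
        oracle = brute_force_info_nce(z, ps.pairs, 0.5)
        assert mine == pytest.approx(oracle, abs=1e-10)

    def test_collinear_positive_reduces_loss(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(8, 4))
        pr = np.array([[0, 1], [2, 3], [4, 5]])
        ps = PairSet(pairs={"rna": pr}, T=3, tau=0.5)
        before = info_nce_loss(Tensor(z), ps).item()
        z2 = z.copy()
        z2[1] = 2.0 * z2[0]  # make pair 0 collinear
        after = info_nce_loss(Tensor(z2), ps).item()
        assert after < before

    def test_single_pair_rejected(self):
        ps = PairSet(pairs={"rna": np.array([[0, 1]])}, T=1, tau=0.5)
        with pytest.raises(ValueError):
            info_nce_loss(Tensor(np.ones((2, 2))), ps)


class TestTriplet:
    def test_hinge_inactive(self):
        z = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 0.0]])
        ts = TripletSet(triplets=np.array([[0, 1, 2]]), H=1, margin=1.0)
        assert triplet_loss(Tensor(z), ts).item() == pytest.approx(0.0, abs=1e-5)

    def test_hinge_active_equal_distances(self):
        z = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ts = TripletSet(triplets=np.array([[0, 1, 2]]), H=1, margin=0.5)
        assert triplet_loss(Tensor(z), ts).item() == pytest.approx(0.5, abs=1e-5)

    def test_mean_over_triplets(self):
        z = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        tri = np.array([[0, 1, 2], [0, 3, 4]])  # hinges 0 and 0.5 at margin 0.5
        ts05 = TripletSet(triplets=tri, H=2, margin=0.5)
        assert triplet_loss(Tensor(z), ts05).item() == pytest.approx(0.25, abs=1e-5)


class TestTotal:
    def test_weighted_sums(self):
        assert total_loss(1, 2, 3, 4, 5, LossWeights(1, 1, 1, 1, 1)).item() == 15
        assert total_loss(1, 2, 3, 4, 5, LossWeights(0, 0, 0, 0, 0)).item() == 0
        assert total_loss(3, 4, 0, 0, 0, LossWeights(2, 1, 0, 0, 0)).item() == 10

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(recon=-1)


def test_losses_permutation_invariant():
    """Reordering cells (with permuted graphs/pairs/triplets) leaves every
    term unchanged."""
    rng = np.random.default_rng(0)
    n = 12
    z = rng.normal(size=(n, 4))
    edges = [(0, 1), (2, 3), (4, 7), (5, 9)]
    g = _graph(n, edges)
    pr = np.array([[0, 1], [2, 3], [4, 7]])
    ps = PairSet(pairs={"rna": pr}, T=3, tau=0.5)
    tri = np.array([[0, 1, 2], [3, 4, 5]])
    ts = TripletSet(triplets=tri, H=2, margin=1.0)
    mu = rng.normal(size=(n, 4))
    nu = rng.uniform(0.5, 2, size=(n, 4))

    perm = rng.permutation(n)
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    zp = z[perm]
    gp = _graph(n, [(inv[i], inv[j]) for i, j in edges])
    psp = PairSet(pairs={"rna": inv[pr]}, T=3, tau=0.5)
    tsp = TripletSet(triplets=inv[tri], H=2, margin=1.0)

    post = GaussianPosterior(Tensor(mu), Tensor(nu))
    post_p = GaussianPosterior(Tensor(mu[perm]), Tensor(nu[perm]))
    assert kl_loss(post).item() == pytest.approx(kl_loss(post_p).item(), rel=1e-12)
    assert graph_loss(Tensor(z), g).item() == pytest.approx(
        graph_loss(Tensor(zp), gp).item(), rel=1e-12
    )
    assert info_nce_loss(Tensor(z), ps).item() == pytest.approx(
        info_nce_loss(Tensor(zp), psp).item(), rel=1e-12
    )
    assert triplet_loss(Tensor(z), ts).item() == pytest.approx(
        triplet_loss(Tensor(zp), tsp).item(), rel=1e-12
    )
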