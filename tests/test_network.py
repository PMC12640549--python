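"""Network components: attention, gated graph convolution, VAE pieces,
the three-term loss, and the training loop."""

import numpy as np
import pytest

from vargg.autodiff import Tensor
from vargg.errors import ParameterError
from vargg.graph import BinaryAdjacency, build_adjacency
from vargg.network import (LossBreakdown, MultiHeadAttention,
                           ResGatedGraphLayer, VarggConfig, VarggModel,
                           compute_loss, corrupt, decode_adjacency, fit,
                           gated_graph_layer, multi_head_attention,
                           reparameterize)


def small_config(**kw):
    base = dict(input_dim=16, attention_heads=(8, 4, 8),
                dae_hidden_dims=(16, 8), graph_hidden_dims=(16,),
                latent_dim=8, epochs=5, seed=0)
    base.update(kw)
    return VarggConfig(**base)


class TestConfig:
    def test_head_divisibility_enforced(self):
        with pytest.raises(ParameterError, match="divisible"):
            small_config(input_dim=10).validate()

    def test_latent_must_match_encoder_width(self):
        with pytest.raises(ParameterError, match="latent_dim"):
            small_config(latent_dim=6).validate()

    def test_defaults_validate(self):
        VarggConfig().validate()


class TestAttention:
    def test_per_head_subspace_dimension(self):
        rng = np.random.default_rng(0)
        mha = MultiHeadAttention(64, 4, rng)
        assert mha.d_k == 16

    def test_attention_rows_sum_to_one(self, rng):
        mha = MultiHeadAttention(12, 3, np.random.default_rng(0))
        scores = mha.attention_scores(Tensor(rng.standard_normal((7, 12))))
        assert np.allclose(scores.data.sum(axis=-1), 1.0)

    def test_single_head_matches_hand_computation(self):
        X = np.array([[1.0, 0], [0, 1], [1, 1]])
        Wq = np.array([[0.5, 0], [0, 0.5]])
        Wk = np.array([[1.0, 0.2], [0.1, 1]])
        Wv = np.array([[0.3, -0.2], [0.4, 0.6]])
        Wo = np.eye(2)
        out = multi_head_attention(X, heads=1,
                                   params=dict(Wq=Wq, Wk=Wk, Wv=Wv, Wo=Wo))
        q, k, v = X @ Wq, X @ Wk, X @ Wv
        s = q @ k.T / np.sqrt(2)
        p = np.exp(s - s.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        assert np.allclose(out, p @ v, atol=1e-10)

    def test_shape_preserved(self, rng):
        X = rng.standard_normal((9, 8))
        assert multi_head_attention(X, heads=2).shape == X.shape

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ParameterError):
            multi_head_attention(rng.standard_normal((4, 6)), heads=4)


class TestDenoisingEncoder:
    def test_identity_configuration(self):
        cfg = small_config(input_dim=8, dae_hidden_dims=(8,), latent_dim=8,
                           use_attention=False)
        model = VarggModel(cfg, np.random.default_rng(0))
        model.enc_layers[0].W.data = np.eye(8)
        model.enc_layers[0].b.data[:] = 0
        X = np.random.default_rng(1).standard_normal((5, 8))
        assert np.allclose(model.encode_dae(Tensor(X)).data, X)

    def test_fixed_seed_bit_identical(self):
        cfg = small_config(use_attention=False)
        X = np.random.default_rng(2).standard_normal((6, 16)).astype(np.float32)
        outs = []
        for _ in range(2):
            model = VarggModel(cfg, np.random.default_rng(42))
            outs.append(model.encode_dae(Tensor(X)).data)
        assert np.array_equal(outs[0], outs[1])


class TestCorrupt:
    def test_sigma_zero_identity(self, rng):
        Z = rng.standard_normal((4, 3))
        assert np.array_equal(corrupt(Z, 0.0, 0), Z)

    def test_inference_mode_identity(self, rng):
        Z = rng.standard_normal((4, 3))
        assert np.array_equal(corrupt(Z, 1.0, 0, training=False), Z)

    def test_moments(self):
        Z = np.zeros((1000, 100))
        noisy = corrupt(Z, 0.5, 7)
        eps = noisy - Z
        assert abs(eps.mean()) < 3 * 0.5 / np.sqrt(eps.size)
        assert abs(eps.std() - 0.5) < 0.005

    def test_seeded_determinism(self, rng):
        Z = rng.standard_normal((5, 5))
        assert np.array_equal(corrupt(Z, 0.3, 11), corrupt(Z, 0.3, 11))


class TestGatedGraphLayer:
    def test_empty_edges_self_term_only(self, rng):
        H = rng.standard_normal((4, 3))
        adj = BinaryAdjacency(4, np.empty((0, 2)), 0, "kdtree", True)
        lyr = ResGatedGraphLayer(3, 3, np.random.default_rng(0))
        out = gated_graph_layer(H, adj, layer=lyr)
        pre = H @ lyr.W1.data + lyr.b.data
        expect = np.where(pre > 0, pre, np.expm1(pre))
        assert np.allclose(out, expect, atol=1e-10)

    def test_two_node_hand_computation(self):
        H = np.array([[1.0, 2], [3, -1]])
        adj = BinaryAdjacency(2, [[0, 1], [1, 0]], 1, "kdtree", True)
        lyr = ResGatedGraphLayer(2, 2, np.random.default_rng(0))
        lyr.W1.data = np.eye(2)
        lyr.W2.data = np.eye(2)
        lyr.W3.data = np.zeros((2, 2))
        lyr.W4.data = np.zeros((2, 2))
        lyr.b.data[:] = 0
        out = gated_graph_layer(H, adj, layer=lyr)
        # gate = sigmoid(0) = 0.5 on every edge
        pre = H + 0.5 * H[[1, 0]]
        expect = np.where(pre > 0, pre, np.expm1(pre))
        assert np.allclose(out, expect, atol=1e-12)

    def test_permutation_equivariance(self, rng):
        H = rng.standard_normal((8, 4))
        adj = build_adjacency(rng.uniform(0, 1, (8, 2)), k=2, symmetrize=True)
        lyr = ResGatedGraphLayer(4, 5, np.random.default_rng(3))
        out = gated_graph_layer(H, adj, layer=lyr)
        perm = rng.permutation(8)
        inv = np.argsort(perm)
        perm_edges = inv[adj.edges]
        adj_p = BinaryAdjacency(8, perm_edges, adj.k, adj.method, True)
        out_p = gated_graph_layer(H[perm], adj_p, layer=lyr)
        assert np.allclose(out_p, out[perm], atol=1e-10)


class TestLatentHeads:
    def test_heads_have_independent_parameters(self, rng):
        cfg = small_config(use_attention=False)
        model = VarggModel(cfg, np.random.default_rng(0))
        H = Tensor(rng.standard_normal((6, 8)).astype(np.float32))
        edges = np.array([[0, 1], [1, 0]])
        _, logvar_before = model.latent_params(H, edges)
        model.mu_head.W1.data += 10.0
        mu_after, logvar_after = model.latent_params(H, edges)
        assert np.array_equal(logvar_before.data, logvar_after.data)
        assert mu_after.data.shape == (6, 8)


class TestReparameterize:
    def test_theta_zero_returns_mu_both_modes(self, rng):
        mu, logvar = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        z0 = np.zeros((4, 3))
        for mode in ("standard", "paper_literal"):
            assert np.allclose(reparameterize(mu, logvar, z0, mode), mu)

    def test_logvar_zero_distinguishes_modes(self, rng):
        mu = rng.standard_normal((4, 3))
        theta = rng.standard_normal((4, 3))
        lv = np.zeros((4, 3))
        assert np.allclose(reparameterize(mu, lv, theta, "paper_literal"), mu)
        assert np.allclose(reparameterize(mu, lv, theta, "standard"), mu + theta)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ParameterError):
            reparameterize(np.zeros(2), np.zeros(2), np.zeros(2), "bogus")


class TestDecoders:
    def test_adjacency_probs_hand_values(self):
        assert np.allclose(decode_adjacency(np.zeros((3, 2))), 0.5)
        z = np.array([[np.sqrt(np.log(3)), 0], [np.sqrt(np.log(3)), 0]])
        assert decode_adjacency(z)[0, 1] == pytest.approx(0.75)

    def test_adjacency_probs_symmetric(self, rng):
        p = decode_adjacency(rng.standard_normal((6, 4)))
        assert np.allclose(p, p.T)

    def test_decoder_depends_only_on_sum(self, rng):
        cfg = small_config(use_attention=False)
        model = VarggModel(cfg, np.random.default_rng(0))
        Z = rng.standard_normal((5, 8)).astype(np.float32)
        Z_E = rng.standard_normal((5, 8)).astype(np.float32)
        a = model.decode_dae(Tensor(Z), Tensor(Z_E)).data
        b = model.decode_dae(Tensor(np.zeros_like(Z)), Tensor(Z + Z_E)).data
        assert np.allclose(a, b, atol=1e-6)
        assert a.shape == (5, 16)


class TestLoss:
    def make_adj(self, n=4):
        edges = [[i, (i + 1) % n] for i in range(n)]
        return BinaryAdjacency(n, edges, 1, "kdtree", False).symmetrize()

    def test_all_perfect_case(self, rng):
        X = rng.standard_normal((4, 3))
        A = self.make_adj()
        probs = A.to_dense()
        lb = compute_loss(X, X, np.zeros((4, 2)), np.zeros((4, 2)), A, probs)
        assert lb.mse == 0 and lb.kl == 0
        assert lb.adj_bce < 1e-4 and lb.total < 1e-4

    def test_kl_hand_value_single_spot(self):
        A = BinaryAdjacency(1, np.empty((0, 2)), 0, "kdtree", True)
        lb = compute_loss(np.zeros((1, 1)), np.zeros((1, 1)),
                          np.array([[1.0]]), np.array([[0.0]]), A,
                          np.zeros((1, 1)))
        assert lb.kl == pytest.approx(0.5)

    def test_weight_gating_reduces_to_mse(self, rng):
        X, Xh = rng.standard_normal((4, 3)), rng.standard_normal((4, 3))
        A = self.make_adj()
        lb = compute_loss(X, Xh, rng.standard_normal((4, 2)),
                          rng.standard_normal((4, 2)), A,
                          rng.uniform(0, 1, (4, 4)), weights=(1.0, 0.0, 0.0))
        assert lb.total == lb.mse

    def test_total_recombines_exactly(self, rng):
        for _ in range(20):
            mse, kl, bce = rng.uniform(0, 10, 3)
            w = tuple(rng.uniform(0, 2, 3))
            lb = LossBreakdown.combine(mse, kl, bce, w)
            assert lb.total == w[0] * mse + w[1] * kl + w[2] * bce

    def test_kl_nonnegative_on_random_grids(self, rng):
        A = self.make_adj()
        for _ in range(50):
            mu = rng.standard_normal((4, 3)) * rng.uniform(0, 3)
            lv = rng.standard_normal((4, 3)) * rng.uniform(0, 3)
            lb = compute_loss(np.zeros((4, 2)), np.zeros((4, 2)), mu, lv, A,
                              np.full((4, 4), 0.5))
            assert lb.kl >= -1e-12


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    coords = np.array([[i, j] for i in range(7) for j in range(7)], float)
    X = rng.standard_normal((49, 16))
    X[:25] += 2.0  # crude two-population structure
    adj = build_adjacency(coords, k=4, symmetrize=True)
    cfg = small_config(epochs=40)
    return X, adj, cfg, fit(X, adj, cfg)


class TestFit:
    def test_loss_decreases(self, fitted):
        _, _, _, res = fitted
        assert res.loss_trace[-1].total < res.loss_trace[5].total

    def test_seeded_determinism(self, fitted):
        X, adj, cfg, res = fitted
        res2 = fit(X, adj, cfg)
        assert np.array_equal(res.latent, res2.latent)
        assert [lb.total for lb in res.loss_trace] == \
               [lb.total for lb in res2.loss_trace]

    def test_trace_length_and_shapes(self, fitted):
        X, adj, cfg, res = fitted
        assert len(res.loss_trace) == cfg.epochs
        assert res.latent.shape == (49, cfg.latent_dim)
        assert res.reconstruction.shape == X.shape
        assert res.adjacency_probs.shape[0] == adj.edges.shape[0]

    def test_zero_epochs_gives_untrained_latent(self, fitted):
        X, adj, cfg, _ = fitted
        import dataclasses
        res = fit(X, adj, dataclasses.replace(cfg, epochs=0))
        assert res.loss_trace == []
        assert np.all(np.isfinite(res.latent))

    def test_ablation_configs_run(self, fitted):
        X, adj, cfg, _ = fitted
        import dataclasses
        for kw in (dict(noise_sigma=0.0), dict(use_attention=False),
                   dict(noise_sigma=0.0, use_attention=False)):
            res = fit(X, adj, dataclasses.replace(cfg, epochs=3, **kw))
            assert np.all(np.isfinite(res.latent))

    def test_fit_result_persists(self, fitted, tmp_path):
        _, _, _, res = fitted
        res.to_dir(tmp_path)
        assert (tmp_path / "latent.tsv").exists()
        assert (tmp_path / "loss.csv").exists()
        assert (tmp_path / "config.yaml").exists()


class TestEncoderEquivariance:
    def test_permuting_spots_permutes_mu(self, rng):
        cfg = small_config(use_attention=True, dtype="float64")
        model = VarggModel(cfg, np.random.default_rng(0))
        n = 10
        X = rng.standard_normal((n, 16))
        adj = build_adjacency(rng.uniform(0, 1, (n, 2)), k=3, symmetrize=True)
        out = model.forward(Tensor(X), adj.edges)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        adj_p = BinaryAdjacency(n, inv[adj.edges], adj.k, adj.method, True)
        out_p = model.forward(Tensor(X[perm]), adj_p.edges)
        assert np.allclose(out_p["mu"].data, out["mu"].data[perm], atol=1e-8)
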