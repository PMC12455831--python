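"""Masked autoencoder: attention, layer forward, masking and SCE loss,
each against independent scalar oracles."""

import numpy as np
import pytest

from kgrn._autodiff import Parameter, Tensor
from kgrn.data_io import ExpressionMatrix
from kgrn.mae import (GatLayerParams, MaeParams, gat_attention_row,
                      gat_layer_forward, mae_forward, mask_features, sce_loss)
from kgrn.trainer import TrainConfig, train


def make_layer(W, a, activation="identity", average=False, slope=0.2):
    W = np.atleast_3d(np.asarray(W, dtype=float))
    if W.ndim == 3 and W.shape[0] != 1 and W.shape[2] == 1:
        pass
    a = np.atleast_2d(np.asarray(a, dtype=float))
    return GatLayerParams(weight=Parameter(W), attn_vector=Parameter(a),
                          heads=W.shape[0], activation=activation,
                          average_heads=average, negative_slope=slope)


def random_layer(rng, in_dim, out_dim, heads, activation="identity",
                 average=False):
    W = rng.normal(size=(heads, in_dim, out_dim))
    a = rng.normal(size=(heads, 2 * out_dim))
    return GatLayerParams(weight=Parameter(W), attn_vector=Parameter(a),
                          heads=heads, activation=activation,
                          average_heads=average)


def gat_oracle(H, adj, params):
    """Node-by-node scalar re-evaluation of the attention layer."""
    n = H.shape[0]
    out = params.out_dim
    heads_out = []
    for h in range(params.heads):
        W = params.weight.data[h]
        a_src = params.attn_vector.data[h, :out]
        a_dst = params.attn_vector.data[h, out:]
        res = np.zeros((n, out))
        for i in range(n):
            nbrs = [j for j in range(n) if adj[i, j]]
            logits = []
            for j in nbrs:
                x = a_src @ (W.T @ H[i]) + a_dst @ (W.T @ H[j])
                logits.append(x if x > 0 else params.negative_slope * x)
            logits = np.array(logits)
            e = np.exp(logits - logits.max())
            alpha = e / e.sum()
            assert abs(alpha.sum() - 1.0) < 1e-12  # Eq-level normalization
            for alpha_j, j in zip(alpha, nbrs):
                res[i] += alpha_j * (W.T @ H[j])
        heads_out.append(res)
    if params.average_heads:
        agg = np.mean(heads_out, axis=0)
    else:
        agg = np.concatenate(heads_out, axis=1)
    if params.activation == "prelu":
        al = float(params.prelu_alpha.data)
        agg = np.where(agg > 0, agg, al * agg)
    return agg


class TestAttentionRow:
    def test_single_neighbor_gets_all_attention(self):
        rng = np.random.default_rng(0)
        layer = random_layer(rng, 3, 2, heads=1)
        a = gat_attention_row(rng.normal(size=3), [rng.normal(size=3)], layer)
        assert a == pytest.approx(1.0)

    def test_identical_neighbors_uniform(self):
        rng = np.random.default_rng(1)
        layer = random_layer(rng, 3, 2, heads=1)
        nbr = rng.normal(size=3)
        a = gat_attention_row(rng.normal(size=3), [nbr.copy() for _ in range(4)],
                              layer)
        np.testing.assert_allclose(a, 0.25)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_softmax_oracle(self, seed):
        rng = np.random.default_rng(seed)
        layer = random_layer(rng, 4, 3, heads=1)
        h_self = rng.normal(size=4)
        nbrs = [rng.normal(size=4) for _ in range(3)]
        a = gat_attention_row(h_self, nbrs, layer)
        # independent logit-then-softmax evaluation
        W = layer.weight.data[0]
        av = layer.attn_vector.data[0]
        logits = []
        for hn in nbrs:
            z = np.concatenate([W.T @ h_self, W.T @ hn])
            x = av @ z
            logits.append(x if x > 0 else 0.2 * x)
        e = np.exp(logits)
        np.testing.assert_allclose(a, e / e.sum(), atol=1e-10)
        assert a.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_neighborhood_errors(self):
        rng = np.random.default_rng(2)
        layer = random_layer(rng, 3, 2, heads=1)
        with pytest.raises(ValueError, match="empty neighborhood"):
            gat_attention_row(rng.normal(size=3), [], layer)


class TestLayerForward:
    def test_identity_setup_preserves_input(self):
        n, d = 4, 3
        layer = make_layer(np.eye(d)[None], np.zeros((1, 2 * d)))
        H = np.random.default_rng(3).normal(size=(n, d))
        out = gat_layer_forward(H, np.eye(n, dtype=int), layer)
        np.testing.assert_allclose(out.data, H, atol=1e-12)

    def test_zero_attention_vector_gives_neighborhood_mean(self):
        # a = 0 makes every logit equal, so alpha is uniform and the
        # output row is the mean of neighbor features (W = I, sigma = id)
        rng = np.random.default_rng(4)
        n, d = 5, 3
        H = rng.normal(size=(n, d))
        adj = np.ones((n, n), dtype=int)
        layer = make_layer(np.eye(d)[None], np.zeros((1, 2 * d)))
        out = gat_layer_forward(H, adj, layer)
        np.testing.assert_allclose(out.data,
                                   np.tile(H.mean(axis=0), (n, 1)), atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    @pytest.mark.parametrize("heads,average", [(1, False), (3, False), (2, True)])
    def test_matches_per_node_oracle(self, seed, heads, average):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            n = int(rng.integers(2, 9))
            adj = (rng.random((n, n)) < 0.5).astype(int)
            np.fill_diagonal(adj, 1)
            H = rng.normal(size=(n, 4))
            layer = random_layer(rng, 4, 3, heads=heads, activation="prelu",
                                 average=average)
            out = gat_layer_forward(H, adj, layer)
            np.testing.assert_allclose(out.data, gat_oracle(H, adj, layer),
                                       atol=1e-8)

    def test_isolated_node_errors(self):
        rng = np.random.default_rng(5)
        layer = random_layer(rng, 2, 2, heads=1)
        adj = np.array([[1, 0], [0, 0]])
        with pytest.raises(ValueError, match="isolated"):
            gat_layer_forward(rng.normal(size=(2, 2)), adj, layer)


class TestMasking:
    def test_ratio_zero_is_identity(self):
        X = np.arange(12.0).reshape(4, 3)
        res = mask_features(X, 0.0, np.zeros(3), seed=0)
        assert res.n_masked == 0
        np.testing.assert_array_equal(res.masked_features, X)

    def test_ratio_one_replaces_every_row(self):
        X = np.arange(12.0).reshape(4, 3)
        token = np.array([9.0, 9.0, 9.0])
        res = mask_features(X, 1.0, token, seed=0)
        assert res.n_masked == 4
        np.testing.assert_array_equal(res.masked_features,
                                      np.tile(token, (4, 1)))

    def test_seed_determinism_and_count(self):
        X = np.random.default_rng(6).normal(size=(10, 5))
        r1 = mask_features(X, 0.5, np.zeros(5), seed=42)
        r2 = mask_features(X, 0.5, np.zeros(5), seed=42)
        assert r1.n_masked == 5
        np.testing.assert_array_equal(r1.masked_nodes, r2.masked_nodes)
        unmasked = np.setdiff1d(np.arange(10), r1.masked_nodes)
        np.testing.assert_array_equal(r1.masked_features[unmasked], X[unmasked])


class TestMaeForward:
    def test_shapes_and_finiteness_untrained(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(6, 5))
        adj = np.ones((6, 6), dtype=int)
        params = MaeParams.init(5, latent_dim=8, encoder_heads=2, rng=rng)
        H, X_rec = mae_forward(X, adj, params)
        assert H.data.shape == (6, 8) and X_rec.data.shape == (6, 5)
        assert np.isfinite(H.data).all() and np.isfinite(X_rec.data).all()

    def test_composition_of_layer_oracles(self):
        # 1-layer linear encoder + decoder on a 3-node path graph equals
        # two sequential gat_layer_forward calls
        rng = np.random.default_rng(8)
        adj = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]])
        X = rng.normal(size=(3, 4))
        enc = random_layer(rng, 4, 6, heads=1)
        dec = random_layer(rng, 6, 4, heads=1, average=True)
        params = MaeParams(encoder_layers=[enc], decoder_layers=[dec],
                           mask_token=Parameter(np.zeros(4)), latent_dim=6)
        H, X_rec = mae_forward(X, adj, params)
        H_ref = gat_layer_forward(X, adj, enc)
        X_ref = gat_layer_forward(H_ref, adj, dec)
        np.testing.assert_allclose(H.data, H_ref.data, atol=1e-12)
        np.testing.assert_allclose(X_rec.data, X_ref.data, atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        n = 6
        X = rng.normal(size=(n, 5))
        adj = (rng.random((n, n)) < 0.5).astype(int)
        adj = adj | adj.T
        np.fill_diagonal(adj, 1)
        params = MaeParams.init(5, latent_dim=4, encoder_heads=2,
                                rng=np.random.default_rng(10))
        perm = rng.permutation(n)
        H1, R1 = mae_forward(X, adj, params)
        H2, R2 = mae_forward(X[perm], adj[np.ix_(perm, perm)], params)
        np.testing.assert_allclose(H2.data, H1.data[perm], atol=1e-10)
        np.testing.assert_allclose(R2.data, R1.data[perm], atol=1e-10)


class TestSceLoss:
    def test_perfect_reconstruction_zero(self):
        X = np.random.default_rng(11).normal(size=(4, 3))
        assert sce_loss(X, X.copy(), [0, 1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_gamma_one_is_two(self):
        X = np.random.default_rng(12).normal(size=(4, 3))
        assert sce_loss(X, -X, [0, 1], gamma=1) == pytest.approx(2.0, abs=1e-6)

    def test_orthogonal_gamma_two_is_one(self):
        X = np.array([[1.0, 0.0]])
        R = np.array([[0.0, 1.0]])
        assert sce_loss(X, R, [0], gamma=2) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("gamma", [1, 2, 3])
    def test_termwise_scalar_oracle(self, gamma):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(5, 6))
        R = rng.normal(size=(5, 6))
        masked = [0, 2, 4]
        expected = np.mean([
            (1 - X[i] @ R[i] / (np.linalg.norm(X[i]) * np.linalg.norm(R[i]))) ** gamma
            for i in masked])
        assert sce_loss(X, R, masked, gamma=gamma) == pytest.approx(expected,
                                                                    abs=1e-8)

    def test_invariant_to_positive_row_rescaling(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(4, 5))
        R = rng.normal(size=(4, 5))
        masked = [1, 3]
        base = sce_loss(X, R, masked, gamma=2)
        scaled = sce_loss(X * 7.0, R * 0.01, masked, gamma=2)
        assert scaled == pytest.approx(base, rel=1e-6)

    def test_empty_masked_set_errors(self):
        X = np.ones((3, 2))
        with pytest.raises(ValueError, match="nonempty"):
            sce_loss(X, X, [])


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_training_reduces_reconstruction_loss(seed, small_bundle):
    """100 optimizer steps on the synthetic fixture lower the SCE loss."""
    cfg = TrainConfig(epochs=100, seed=seed, lambda_kge=0.0, knn_k=5)
    _, history = train(small_bundle["expr"], None, cfg)
    assert history[-1]["l_mae"] < history[0]["l_mae"]
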