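"""Attention network: oracle equivalence, invariants, gradients, checkpoints.

The oracle here is a deliberately naive pure-Python re-implementation of the
whole forward pass (explicit loops, explicit softmax normalization by
summation) kept independent of the vectorized implementation it checks.
"""

import math

import numpy as np
import pytest

from solugat.gat import (GATLayerParams, GATModelConfig, GATParams,
                         attention_coefficients, backward_batch,
                         forward_batch, gat_layer_forward, init_params,
                         load_checkpoint, mlp_predict, model_forward,
                         multi_head_forward, readout_pool, save_checkpoint)

from conftest import random_graph


# ---------------------------------------------------------------------------
# scalar-loop oracle
# ---------------------------------------------------------------------------

def oracle_elu(x):
    return x if x > 0 else math.exp(x) - 1.0


def oracle_attention(H, W, a_src, a_dst, A, slope):
    """Explicit e_ij / alpha_ij for one head; dense loops, no stabilization."""
    L = len(H)
    Z = [[sum(W[p][f] * H[i][f] for f in range(len(H[0])))
          for p in range(len(W))] for i in range(L)]
    alpha = [[0.0] * L for _ in range(L)]
    for i in range(L):
        logits = {}
        for j in range(L):
            if not A[i][j]:
                continue
            e = (sum(a_src[p] * Z[i][p] for p in range(len(a_src)))
                 + sum(a_dst[p] * Z[j][p] for p in range(len(a_dst))))
            logits[j] = e if e > 0 else slope * e
        denom = sum(math.exp(v) for v in logits.values())
        for j, v in logits.items():
            alpha[i][j] = math.exp(v) / denom
    return Z, alpha


def oracle_forward(A, H, params, config):
    """Whole model: per-head attention, ELU, concatenation, pooling, MLP."""
    L = len(H)
    nodes = [list(map(float, row)) for row in np.asarray(H)]
    for layer in params.layers:
        new_nodes = [[] for _ in range(L)]
        for k in range(layer.heads):
            Z, alpha = oracle_attention(
                nodes, layer.W[k].tolist(), layer.a_src[k].tolist(),
                layer.a_dst[k].tolist(), np.asarray(A).tolist(),
                config.leaky_slope)
            for i in range(L):
                for p in range(layer.head_dim):
                    agg = sum(alpha[i][j] * Z[j][p] for j in range(L))
                    new_nodes[i].append(oracle_elu(agg))
        nodes = new_nodes
    pooled = [sum(nodes[i][c] for i in range(L)) / L
              for c in range(len(nodes[0]))]
    u = sum(w * p for w, p in zip(params.w_mlp.tolist(), pooled)) \
        + float(params.b_mlp)
    return max(0.0, u), nodes


def small_config(seed=0, in_features=7, heads=3, head_dim=4, layers=2):
    return GATModelConfig(in_features=in_features, num_layers=layers,
                          heads=heads, hidden_channels=heads * head_dim,
                          seed=seed)


def random_instance(rng, L=None, config=None):
    config = config or small_config(seed=int(rng.integers(2 ** 31)))
    L = L or int(rng.integers(1, 11))
    A = random_graph(rng, L)
    H = rng.normal(size=(L, config.in_features))
    params = init_params(config)
    # random MLP weights (init leaves w at zero)
    params.w_mlp = rng.normal(0, 0.3, size=config.hidden_channels)
    params.b_mlp = np.array(rng.normal())
    return A, H, params, config


class TestAttentionCoefficients:
    def test_single_node_alpha_is_one(self, rng):
        config = small_config()
        params = init_params(config)
        H = rng.normal(size=(1, config.in_features))
        alpha = attention_coefficients(H, params.layers[0], np.ones((1, 1)))
        np.testing.assert_allclose(alpha[:, 0, 0], 1.0)

    def test_zero_features_give_uniform_attention(self):
        config = small_config()
        params = init_params(config)
        A = np.ones((3, 3), dtype=bool)
        alpha = attention_coefficients(np.zeros((3, config.in_features)),
                                       params.layers[0], A)
        np.testing.assert_allclose(alpha, 1.0 / 3.0)

    def test_rows_are_distributions_and_masked(self, rng):
        for _ in range(10):
            A, H, params, config = random_instance(rng)
            for layer in params.layers[:1]:
                alpha = attention_coefficients(H, layer, A,
                                               config.leaky_slope)
                np.testing.assert_allclose(alpha.sum(axis=2), 1.0,
                                           atol=1e-12)
                assert (alpha >= 0).all() and (alpha <= 1).all()
                assert (alpha[:, ~A] == 0).all()

    def test_matches_dense_loop_oracle(self, rng):
        A, H, params, config = random_instance(rng, L=6)
        layer = params.layers[0]
        alpha = attention_coefficients(H, layer, A, config.leaky_slope)
        for k in range(layer.heads):
            _, alpha_o = oracle_attention(
                H.tolist(), layer.W[k].tolist(), layer.a_src[k].tolist(),
                layer.a_dst[k].tolist(), A.tolist(), config.leaky_slope)
            np.testing.assert_allclose(alpha[k], alpha_o, atol=1e-10)


class TestLayerForward:
    def test_k1_multi_head_equals_single_head(self, rng):
        config = small_config(heads=1, head_dim=5)
        A, H, params, _ = random_instance(rng, L=5, config=config)
        per_head = gat_layer_forward(H, params.layers[0], A)
        concat = multi_head_forward(H, params.layers[0], A)
        np.testing.assert_allclose(per_head[:, 0, :], concat)

    def test_duplicated_heads_duplicate_output(self, rng):
        config = small_config(heads=2, head_dim=4)
        A, H, params, _ = random_instance(rng, L=5, config=config)
        layer = params.layers[0]
        layer.W[1] = layer.W[0]
        layer.a_src[1] = layer.a_src[0]
        layer.a_dst[1] = layer.a_dst[0]
        out = multi_head_forward(H, layer, A)
        np.testing.assert_allclose(out[:, :4], out[:, 4:])

    def test_sixteen_heads_of_64_give_1024_channels(self, rng):
        config = GATModelConfig(in_features=10, num_layers=1, heads=16,
                                hidden_channels=1024)
        params = init_params(config)
        H = rng.normal(size=(4, 10))
        out = multi_head_forward(H, params.layers[0], random_graph(rng, 4))
        assert out.shape == (4, 1024)

    def test_hidden_not_divisible_by_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            GATModelConfig(heads=16, hidden_channels=1000)

    def test_zero_features_output_sigma_of_zero(self, rng):
        config = small_config()
        params = init_params(config)
        A = random_graph(rng, 4)
        out = multi_head_forward(np.zeros((4, config.in_features)),
                                 params.layers[0], A)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)


class TestReadoutAndMLP:
    def test_single_node_pool_identity(self, rng):
        v = rng.normal(size=(1, 8))
        np.testing.assert_allclose(readout_pool(v), v[0])

    def test_opposite_vectors_pool_to_zero(self, rng):
        v = rng.normal(size=8)
        np.testing.assert_allclose(readout_pool(np.vstack([v, -v])),
                                   np.zeros(8), atol=1e-15)

    def test_pool_permutation_invariant(self, rng):
        M = rng.normal(size=(7, 5))
        perm = rng.permutation(7)
        np.testing.assert_allclose(readout_pool(M), readout_pool(M[perm]))

    def test_relu_clamp(self):
        assert mlp_predict(np.zeros(4), np.zeros(4), -1.0) == 0.0
        assert mlp_predict(np.zeros(4), np.zeros(4), 0.7) == pytest.approx(0.7)

    def test_matches_dot_product(self, rng):
        w = rng.normal(size=6)
        p = rng.normal(size=6)
        expected = max(0.0, sum(w[i] * p[i] for i in range(6)) + 0.3)
        assert mlp_predict(p, w, 0.3) == pytest.approx(expected, rel=1e-12)


class TestModelForward:
    def test_single_node_graph_runs(self, rng):
        A, H, params, config = random_instance(rng, L=1)
        S = model_forward(np.ones((1, 1)), H, params, config)
        assert np.isfinite(S) and S >= 0

    def test_all_zero_parameters_give_relu_bias(self, rng):
        A, H, params, config = random_instance(rng, L=5)
        for layer in params.layers:
            layer.W[:] = 0
            layer.a_src[:] = 0
            layer.a_dst[:] = 0
        params.w_mlp[:] = 0
        params.b_mlp = np.array(0.7)
        assert model_forward(A, H, params, config) == pytest.approx(0.7)
        params.b_mlp = np.array(-0.7)
        assert model_forward(A, H, params, config) == 0.0

    def test_matches_oracle(self, rng):
        for _ in range(10):
            A, H, params, config = random_instance(rng)
            S = model_forward(A, H, params, config)
            S_oracle, _ = oracle_forward(A, H, params, config)
            assert S == pytest.approx(S_oracle, rel=1e-9, abs=1e-9)

    def test_permutation_invariance_and_equivariance(self, rng):
        for _ in range(5):
            A, H, params, config = random_instance(rng, L=8)
            perm = rng.permutation(8)
            S1, _, nodes1 = forward_batch([(A, H)], params, config)
            S2, _, nodes2 = forward_batch(
                [(A[np.ix_(perm, perm)], H[perm])], params, config)
            assert S1[0] == pytest.approx(S2[0], rel=1e-9, abs=1e-12)
            np.testing.assert_allclose(nodes1[perm], nodes2, atol=1e-9)

    def test_masking_sensitivity(self, rng):
        config = small_config()
        params = init_params(config)
        params.w_mlp = rng.normal(size=config.hidden_channels)
        H = rng.normal(size=(6, config.in_features))
        A = np.eye(6, dtype=bool)
        A[0, 1] = A[1, 0] = True
        S_base = model_forward(A, H, params, config)
        # adding an edge changes the output
        A2 = A.copy()
        A2[2, 3] = A2[3, 2] = True
        assert model_forward(A2, H, params, config) != pytest.approx(
            S_base, abs=1e-12)

    def test_softmax_stabilization_on_large_features(self, rng):
        A, H, params, config = random_instance(rng, L=6)
        S = model_forward(A, H * 1e4, params, config)
        assert np.isfinite(S)

    def test_feature_width_mismatch_rejected(self, rng):
        A, H, params, config = random_instance(rng, L=4)
        with pytest.raises(ValueError, match="feature width"):
            model_forward(A, H[:, :-1], params, config)


class TestGradients:
    def test_finite_difference_agreement(self, rng):
        A, H, params, config = random_instance(rng, L=6)
        # keep the ReLU head away from its kink so central differences are valid
        params.b_mlp = np.array(2.0)
        batch = [(A, H)]
        _, cache, _ = forward_batch(batch, params, config, want_cache=True)
        grads = backward_batch(cache, np.ones(1))
        values = params.as_dict()
        eps = 1e-6
        checked = 0
        for name, arr in values.items():
            flat = np.atleast_1d(arr)
            for _ in range(4):
                idx = tuple(rng.integers(0, s) for s in flat.shape)
                orig = flat[idx]
                flat[idx] = orig + eps
                S_plus, _, _ = forward_batch(batch, params, config)
                flat[idx] = orig - eps
                S_minus, _, _ = forward_batch(batch, params, config)
                flat[idx] = orig
                fd = float(S_plus[0] - S_minus[0]) / (2 * eps)
                an = float(np.atleast_1d(grads[name])[idx])
                if abs(fd) < 1e-10 and abs(an) < 1e-10:
                    continue
                assert abs(fd - an) / max(abs(fd), abs(an)) < 1e-4
                checked += 1
        assert checked > 10


def test_checkpoint_round_trip_bit_exact(tmp_path, rng):
    A, H, params, config = random_instance(rng, L=5)
    path = tmp_path / "model.npz"
    save_checkpoint(path, params, config, feature_mode="esm",
                    extra={"note": "t"})
    params2, config2, meta = load_checkpoint(path)
    assert config2 == config
    assert meta["feature_mode"] == "esm"
    for (k1, v1), (k2, v2) in zip(params.as_dict().items(),
                                  params2.as_dict().items()):
        assert k1 == k2
        np.testing.assert_array_equal(v1, v2)
    assert model_forward(A, H, params2, config2) == model_forward(
        A, H, params, config)
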