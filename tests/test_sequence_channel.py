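"""Attention channel vs brute-force oracles of the encoder equations."""

import numpy as np
import pytest

from adrnet.autodiff import Tensor
from adrnet.errors import ConfigurationError, FeaturizationError
from adrnet.featurize import SEQUENCE_LENGTH, fp2_hex_sequence
from adrnet.sequence_channel import (
    EncoderParams,
    attention_weights,
    embed_and_norm,
    feedforward_project,
    init_encoder_params,
    multi_head_encode,
    self_attention,
    sequence_encode_batch,
)


def small_params(seq_len=8, dim_prime=6, n_heads=2, dim_ff=10, out_dim=5, seed=0):
    return init_encoder_params(
        dim_prime=dim_prime,
        n_heads=n_heads,
        dim_ff=dim_ff,
        out_dim=out_dim,
        seq_len=seq_len,
        dropout_rate=0.0,
        seed=seed,
        dtype=np.float64,
    )


def oracle_head(E: np.ndarray, Wq, Wk, Wv) -> np.ndarray:
    """Double-loop scaled dot-product attention for one head."""
    L, _ = E.shape
    d_v = Wq.shape[1]
    Q, K, V = E @ Wq, E @ Wk, E @ Wv
    out = np.zeros((L, d_v))
    for s in range(L):
        scores = np.array([Q[s] @ K[j] / np.sqrt(d_v) for j in range(L)])
        scores -= scores.max()
        alpha = np.exp(scores) / np.exp(scores).sum()
        out[s] = sum(alpha[j] * V[j] for j in range(L))
    return out


def oracle_layer_norm(x: np.ndarray, gamma, beta, eps) -> np.ndarray:
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps) * gamma + beta


class TestEmbedAndNorm:
    def test_rows_standardized(self):
        params = small_params()
        tokens = np.array([0, 3, 7, 2, 15, 9, 1, 4])
        E = embed_and_norm(tokens, params).data
        np.testing.assert_allclose(E.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(E.var(axis=1), 1.0, atol=1e-3)

    def test_constant_embedding_row_maps_to_beta(self):
        params = small_params()
        params.embedding.data[5] = 2.0  # zero-variance embedding row
        E = embed_and_norm(np.array([5] * 8), params).data
        np.testing.assert_allclose(E, np.tile(params.ln1_beta.data, (8, 1)), atol=1e-6)

    def test_real_sequence_shape(self):
        params = init_encoder_params(
            dim_prime=8, n_heads=2, dim_ff=16, out_dim=4, seed=1, dtype=np.float64
        )
        seq = fp2_hex_sequence("CC(=O)Oc1ccccc1C(=O)O")
        E = embed_and_norm(seq, params)
        assert E.shape == (SEQUENCE_LENGTH, 8)

    def test_token_outside_alphabet_rejected(self):
        with pytest.raises(FeaturizationError):
            embed_and_norm(np.array([0, 16, 1]), small_params())


class TestSelfAttention:
    def test_identical_rows_give_uniform_attention(self):
        params = small_params()
        E = Tensor(np.tile(np.linspace(-1, 1, 6), (8, 1)))
        alpha = attention_weights(E, params, 0).data
        np.testing.assert_allclose(alpha, 1.0 / 8, atol=1e-12)

    def test_uniform_attention_at_full_length(self):
        params = init_encoder_params(
            dim_prime=8, n_heads=2, dim_ff=16, out_dim=4, seed=3, dtype=np.float64
        )
        E = Tensor(np.tile(np.linspace(-1, 1, 8), (SEQUENCE_LENGTH, 1)))
        alpha = attention_weights(E, params, 0).data
        np.testing.assert_allclose(alpha, 1.0 / SEQUENCE_LENGTH, atol=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_rows_sum_to_one(self, seed):
        params = small_params(seed=seed)
        E = Tensor(np.random.default_rng(seed).normal(size=(8, 6)))
        for h in range(params.n_heads):
            alpha = attention_weights(E, params, h).data
            assert (alpha >= 0).all()
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_oracle(self, seed):
        params = small_params(seed=seed)
        rng = np.random.default_rng(seed + 50)
        E = rng.normal(size=(8, 6))
        for h in range(params.n_heads):
            expected = oracle_head(
                E,
                params.Wq.data[h],
                params.Wk.data[h],
                params.Wv.data[h],
            )
            got = self_attention(Tensor(E), params, h).data
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            self_attention(Tensor(np.zeros((8, 5))), small_params(), 0)

    def test_bad_head_index_rejected(self):
        with pytest.raises(ConfigurationError):
            self_attention(Tensor(np.zeros((8, 6))), small_params(), 2)


class TestMultiHeadEncode:
    def test_two_heads_equal_manual_concat(self):
        params = small_params(seed=9)
        rng = np.random.default_rng(1)
        E = rng.normal(size=(8, 6))
        manual = np.concatenate(
            [
                oracle_head(E, params.Wq.data[h], params.Wk.data[h], params.Wv.data[h])
                for h in range(2)
            ],
            axis=1,
        )
        expected = oracle_layer_norm(
            manual @ params.Wo.data + E,
            params.ln2_gamma.data,
            params.ln2_beta.data,
            params.eps,
        )
        got = multi_head_encode(Tensor(E), params).data
        np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_single_head_identity_wo(self):
        params = small_params(n_heads=1, seed=4)
        params.Wo.data = np.eye(6)
        rng = np.random.default_rng(2)
        E = rng.normal(size=(8, 6))
        head = oracle_head(E, params.Wq.data[0], params.Wk.data[0], params.Wv.data[0])
        expected = oracle_layer_norm(
            head + E, params.ln2_gamma.data, params.ln2_beta.data, params.eps
        )
        np.testing.assert_allclose(
            multi_head_encode(Tensor(E), params).data, expected, atol=1e-9
        )

    def test_zero_weights_residual_passthrough(self):
        params = small_params(seed=5)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            getattr(params, name).data = np.zeros_like(getattr(params, name).data)
        rng = np.random.default_rng(3)
        E = rng.normal(size=(8, 6))
        expected = oracle_layer_norm(
            E, params.ln2_gamma.data, params.ln2_beta.data, params.eps
        )
        np.testing.assert_allclose(
            multi_head_encode(Tensor(E), params).data, expected, atol=1e-12
        )

    def test_permutation_equivariance(self):
        # no positional encoding: permuting token positions permutes rows
        params = small_params(seed=6)
        rng = np.random.default_rng(4)
        E = rng.normal(size=(8, 6))
        perm = rng.permutation(8)
        out = multi_head_encode(Tensor(E), params).data
        out_perm = multi_head_encode(Tensor(E[perm]), params).data
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-9)

    def test_dv_times_heads_must_equal_dim_prime(self):
        with pytest.raises(ConfigurationError):
            small_params(dim_prime=7, n_heads=2)


class TestFeedforwardProject:
    def test_zero_final_layer_gives_zero_output(self):
        params = small_params(seed=7)
        params.W_layer2.data = np.zeros_like(params.W_layer2.data)
        out = feedforward_project(Tensor(np.random.default_rng(0).normal(size=(8, 6))), params)
        np.testing.assert_array_equal(out.data, np.zeros(5))

    def test_eval_mode_deterministic(self):
        params = small_params(seed=8)
        O = np.random.default_rng(1).normal(size=(8, 6))
        a = feedforward_project(Tensor(O), params).data
        b = feedforward_project(Tensor(O), params).data
        np.testing.assert_array_equal(a, b)

    def test_identity_construction_matches_closed_form(self):
        # unit running stats, identity affines, identity-padded weights:
        # the output is LeakyReLU of the flattened input's leading slice
        params = small_params(seq_len=2, dim_prime=3, n_heads=1, dim_ff=6, out_dim=4)
        params.W_layer1.data = np.eye(6)
        params.W_layer2.data = np.eye(6)[:, :4]
        O = np.random.default_rng(5).normal(size=(2, 3))
        out = feedforward_project(Tensor(O), params).data
        flat = O.reshape(-1)
        scale = 1.0 / np.sqrt(1.0 + params.eps)  # running var 1 + eps
        expected = np.where(flat[:4] * scale > 0, flat[:4] * scale, 0.01 * flat[:4] * scale)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_batchnorm_training_standardizes_hidden(self):
        params = small_params(seed=10)
        rng = np.random.default_rng(6)
        O = rng.normal(size=(16, 8, 6))
        feedforward_project(Tensor(O), params, training=True, rng=rng)
        # running stats moved away from their (0, 1) initialization
        assert not np.allclose(params.bn_running_mean, 0.0)


class TestFullChannel:
    def test_eval_deterministic_on_fixed_input(self):
        params = init_encoder_params(
            dim_prime=8, n_heads=2, dim_ff=16, out_dim=4, seed=11, dtype=np.float64
        )
        tokens = np.random.default_rng(7).integers(0, 16, (3, SEQUENCE_LENGTH))
        a = sequence_encode_batch(tokens, params).data
        b = sequence_encode_batch(tokens, params).data
        np.testing.assert_array_equal(a, b)
        assert a.shape == (3, 4)

    def test_training_dropout_changes_output(self):
        params = init_encoder_params(
            dim_prime=8,
            n_heads=2,
            dim_ff=16,
            out_dim=4,
            dropout_rate=0.5,
            seed=12,
            dtype=np.float64,
        )
        tokens = np.random.default_rng(8).integers(0, 16, (4, SEQUENCE_LENGTH))
        eval_out = sequence_encode_batch(tokens, params).data
        train_out = sequence_encode_batch(
            tokens, params, training=True, rng=np.random.default_rng(0)
        ).data
        assert not np.allclose(eval_out, train_out)
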