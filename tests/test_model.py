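"""Network building blocks: convolution triplets, BiGRU, scaled
dot-product attention, the full forward pass, and parameter counting."""

import numpy as np
import pytest

from cbgm._autograd import Tensor, cross_entropy
from cbgm.exceptions import ConfigError
from cbgm.model import (
    GRU,
    AttentionParams,
    CBGMModel,
    Conv1d,
    ModelConfig,
    attention_head,
    count_parameters,
    load_weights,
    multi_head,
    save_weights,
)


class TestConvBlock:
    def test_identity_kernel_passthrough(self, rng):
        conv = Conv1d(1, 1, 3, rng)
        conv.weight.data[...] = 0.0
        conv.weight.data[1, 0, 0] = 1.0  # delta at kernel center
        conv.bias.data[...] = 0.0
        x = rng.normal(size=(2, 50, 1)).astype(np.float32)
        out = conv(Tensor(x))
        assert np.allclose(out.data, x, atol=1e-6)

    def test_same_padding_and_pool_shape_arithmetic(self, rng):
        x = Tensor(rng.normal(size=(4, 300, 1)))
        out = Conv1d(1, 8, 5, rng)(x).max_pool1d(2)
        assert out.shape == (4, 150, 8)

    def test_zero_input_zero_preactivation(self, rng):
        conv = Conv1d(1, 4, 5, rng)
        conv.bias.data[...] = 0.0
        assert np.allclose(conv(Tensor(np.zeros((1, 32, 1)))).data, 0.0)

    def test_input_shorter_than_kernel_rejected(self, rng):
        with pytest.raises(ValueError):
            Conv1d(1, 4, 5, rng)(Tensor(np.zeros((1, 3, 1))))

    def test_conv_backward_matches_finite_differences(self, rng):
        x = Tensor(rng.normal(size=(1, 12, 2)), requires_grad=True)
        conv = Conv1d(2, 3, 3, rng)
        loss = (conv(x) * conv(x)).sum()
        loss.backward()
        eps, i = 1e-3, (0, 5, 1)
        for sign in (1,):
            xp = x.data.copy(); xp[i] += eps
            xm = x.data.copy(); xm[i] -= eps
            lp = float((conv(Tensor(xp)) * conv(Tensor(xp))).sum().data)
            lm = float((conv(Tensor(xm)) * conv(Tensor(xm))).sum().data)
            fd = (lp - lm) / (2 * eps)
        assert abs(fd - x.grad[i]) / (abs(fd) + 1e-6) < 1e-2


class TestBiGRU:
    def test_output_width_is_twice_hidden(self, rng):
        gru = GRU(8, 64, rng, bidirectional=True)
        out = gru(Tensor(rng.normal(size=(2, 5, 8))))
        assert out.shape == (2, 5, 128)

    def test_single_timestep_halves_agree(self, rng):
        gru = GRU(4, 6, rng, bidirectional=True)
        gru.dirs[1] = gru.dirs[0]  # share weights across directions
        out = gru(Tensor(rng.normal(size=(3, 1, 4)))).data
        assert np.allclose(out[:, :, :6], out[:, :, 6:], atol=1e-6)

    def test_reversal_property_with_shared_weights(self, rng):
        """With shared weights, the forward pass over the reversed input
        equals the reversed backward half of the output."""
        gru = GRU(4, 6, rng, bidirectional=True)
        gru.dirs[1] = gru.dirs[0]
        x = rng.normal(size=(2, 7, 4))
        out = gru(Tensor(x)).data
        out_rev = gru(Tensor(x[:, ::-1, :])).data
        assert np.allclose(out_rev[:, :, :6], out[:, ::-1, 6:], atol=1e-5)

    def test_empty_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            GRU(4, 6, rng)(Tensor(np.zeros((1, 0, 4))))


class TestAttention:
    def test_single_timestep_weight_is_one(self, rng):
        x = rng.normal(size=(1, 1, 4))
        w = [rng.normal(size=(4, 2)) for _ in range(3)]
        out, weights = attention_head(Tensor(x), *map(Tensor, w))
        assert np.allclose(weights.data, 1.0, atol=1e-7)
        assert np.allclose(out.data, x @ w[2], atol=1e-5)

    def test_identity_projection_closed_form(self):
        """X = I2, identity projections, d_k = 2: each weight row is the
        softmax of [1/sqrt(2), 0] (hand-computed)."""
        eye = np.eye(2)
        out, weights = attention_head(
            Tensor(eye[None]), Tensor(eye), Tensor(eye), Tensor(eye)
        )
        a = np.exp(1 / np.sqrt(2)) / (np.exp(1 / np.sqrt(2)) + 1.0)
        expected = np.array([[a, 1 - a], [1 - a, a]])
        assert np.allclose(weights.data[0], expected, atol=1e-6)
        assert np.allclose(out.data[0], expected @ eye, atol=1e-6)

    def test_rows_sum_to_one_for_random_inputs(self, rng):
        for _ in range(100):
            x = Tensor(rng.normal(size=(1, 6, 8)))
            w = [Tensor(rng.normal(size=(8, 4))) for _ in range(3)]
            _, weights = attention_head(x, *w)
            assert np.allclose(weights.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_multi_head_reduces_to_single_head(self, rng):
        x = Tensor(rng.normal(size=(2, 5, 8)))
        w = [Tensor(rng.normal(size=(8, 8))) for _ in range(3)]
        params = AttentionParams([w[0]], [w[1]], [w[2]], Tensor(np.eye(8)))
        mh, _ = multi_head(x, params, h=1)
        sh, _ = attention_head(x, w[0], w[1], w[2])
        assert np.allclose(mh.data, sh.data, atol=1e-6)

    def test_head_permutation_with_permuted_output_blocks(self, rng):
        """Permuting head order while permuting W_o's row blocks the same
        way leaves the output unchanged."""
        d, h, dk = 8, 4, 2
        x = Tensor(rng.normal(size=(1, 5, d)))
        wq = [Tensor(rng.normal(size=(d, dk))) for _ in range(h)]
        wk = [Tensor(rng.normal(size=(d, dk))) for _ in range(h)]
        wv = [Tensor(rng.normal(size=(d, dk))) for _ in range(h)]
        wo = rng.normal(size=(h * dk, d))
        out1, _ = multi_head(x, AttentionParams(wq, wk, wv, Tensor(wo)), h)
        perm = [2, 0, 3, 1]
        wo_p = np.concatenate([wo[i * dk : (i + 1) * dk] for i in perm])
        out2, _ = multi_head(
            x,
            AttentionParams(
                [wq[i] for i in perm], [wk[i] for i in perm],
                [wv[i] for i in perm], Tensor(wo_p),
            ),
            h,
        )
        assert np.allclose(out1.data, out2.data, atol=1e-5)

    def test_concat_width_before_projection(self, rng):
        cfg = ModelConfig()
        assert cfg.n_heads == 8 and cfg.d_k * cfg.n_heads == 128

    def test_divisibility_enforced(self):
        with pytest.raises(ConfigError):
            ModelConfig(n_heads=7)


class TestForward:
    def test_probabilities_on_simplex(self, rng):
        m = CBGMModel(ModelConfig(), seed=0)
        out = m.forward(rng.normal(size=(8, 300)))
        assert np.all(out.probabilities >= 0)
        assert np.allclose(out.probabilities.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_is_deterministic(self, rng):
        m = CBGMModel(ModelConfig(), seed=0)
        x = rng.normal(size=(2, 300))
        a = m.forward(x).probabilities
        b = m.forward(x).probabilities
        assert np.array_equal(a, b)

    def test_layer_census_is_thirteen(self):
        m = CBGMModel(ModelConfig(), seed=0)
        census = m.layer_census()
        assert len(census) == 13
        assert census.count("bigru") == 1 and census.count("attention") == 1

    def test_wrong_input_length_rejected(self):
        m = CBGMModel(ModelConfig(), seed=0)
        with pytest.raises(ValueError):
            m.forward(np.zeros((1, 299)))

    def test_gradient_reaches_every_parameter(self, rng):
        m = CBGMModel(ModelConfig(), seed=3)
        logits = m.forward_tensor(
            rng.normal(size=(4, 300)), train=True, rng=np.random.default_rng(0)
        )
        cross_entropy(logits, np.array([0, 1, 2, 3])).backward()
        for p in m.parameters():
            assert p.grad is not None and np.abs(p.grad).sum() > 0

    def test_feature_length_shape_arithmetic(self):
        # 300 -> 150 -> 75 -> 37 through the three pooling stages
        assert ModelConfig().feature_length() == 37


class TestParameterCount:
    def test_ablated_variants_are_strictly_smaller(self):
        full = count_parameters(ModelConfig())
        no_att = count_parameters(ModelConfig(use_attention=False))
        no_gru = count_parameters(
            ModelConfig(use_bigru=False, d_model=128)
        )
        assert no_att < full and no_gru < full

    def test_closed_form_census(self):
        """Hand arithmetic: conv K*Cin*F + F weights + 2F batch-norm per
        triplet, 3 gates x (in*H + H^2 + H) per GRU direction, 3h(d*dk)
        + d^2 attention projections, and the dense head."""
        cfg = ModelConfig()
        expected = 0
        cin = 1
        for f, k, _ in cfg.conv_blocks:
            expected += k * cin * f + f + 2 * f
            cin = f
        H = cfg.gru_hidden
        expected += 2 * 3 * (cin * H + H * H + H)
        d, dk = cfg.d_model, cfg.d_k
        expected += 3 * cfg.n_heads * d * dk + d * d
        expected += cfg.feature_length() * d * 5 + 5
        assert count_parameters(cfg) == expected


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        m = CBGMModel(ModelConfig(), seed=5)
        x = rng.normal(size=(2, 300))
        before = m.forward(x).probabilities
        path = str(tmp_path / "w.npz")
        save_weights(m, path)
        m2 = load_weights(path)
        assert np.allclose(m2.forward(x).probabilities, before, atol=1e-7)
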