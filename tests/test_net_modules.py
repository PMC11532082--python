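"""Algebraic contracts of the fusion building blocks (FCN block, FEM, FIM,
cross-attention, MLFM)."""

import math

import numpy as np
import pytest

from neurofuse.net.modules import (
    FCNBlock,
    FEM,
    FEMSpatial,
    FIM,
    MLFM,
    cross_attention,
    group_sizes,
)
from neurofuse.nn.tensor import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestFCNBlock:
    def test_hidden_dims_follow_half_quarter_rule(self, rng):
        block = FCNBlock(43, 256, rng)
        assert block.hidden_dims == (21, 10)
        out = block(Tensor(rng.normal(size=(2, 43))))
        assert out.shape == (2, 256)

    def test_minimum_hidden_width_is_four(self, rng):
        block = FCNBlock(8, 16, rng)
        assert block.hidden_dims == (4, 4)

    def test_small_input_rejected(self, rng):
        with pytest.raises(ValueError):
            FCNBlock(3, 16, rng)

    def test_zero_weights_give_zero_output(self, rng):
        block = FCNBlock(8, 16, rng)
        block.zero_all_parameters()
        block.eval()
        out = block(Tensor(np.zeros((3, 8))))
        assert np.allclose(out.data, 0.0)

    @pytest.mark.parametrize("pair", [(43, 64), (16, 32), (128, 512)])
    def test_output_matches_paired_channel_count(self, rng, pair):
        in_dim, out_dim = pair
        out = FCNBlock(in_dim, out_dim, rng)(Tensor(rng.normal(size=(2, in_dim))))
        assert out.shape == (2, out_dim)


class TestGroupSizes:
    def test_equal_split(self):
        assert group_sizes(12, 3) == [4, 4, 4]

    def test_remainder_goes_to_first_groups(self):
        assert group_sizes(13, 3) == [5, 4, 4]
        assert group_sizes(7, 3) == [3, 2, 2]

    def test_more_groups_than_channels(self):
        assert group_sizes(2, 3) == [1, 1]


class TestFEM:
    def test_weights_strictly_in_unit_interval(self, rng):
        fem = FEM(16, 3, rng)
        w = fem.weights(Tensor(rng.normal(size=(5, 16)))).data
        assert (w > 0).all() and (w < 1).all()

    def test_zeroed_second_fc_gives_half_normalized_input(self, rng):
        # W_f = sigmoid(0) = 0.5 when fc2 is zeroed, so F_e = 0.5 * norm(F)
        fem = FEM(16, 3, rng)
        fem.fc2.weight.data[...] = 0.0
        fem.fc2.bias.data[...] = 0.0
        fem.eval()  # running stats: norm(F) = F
        f = Tensor(rng.normal(size=(4, 16)))
        _, state = fem(f, return_state=True)
        assert np.allclose(state["W_f"].data, 0.5)
        assert np.allclose(state["F_e"].data, 0.5 * f.data, atol=1e-10)

    @pytest.mark.parametrize("channels", [6, 16, 33])
    def test_output_length_equals_input_length(self, rng, channels):
        fem = FEM(channels, 3, rng)
        out = fem(Tensor(rng.normal(size=(2, channels))))
        assert out.shape == (2, channels)


class TestFEMSpatial:
    def test_output_shape_preserved(self, rng):
        fem = FEMSpatial(8, 3, rng)
        x = Tensor(rng.normal(size=(2, 8, 5, 5)))
        assert fem(x).shape == (2, 8, 5, 5)

    def test_constant_map_scale_matches_vector_fem(self, rng):
        # constant-over-space input: pooling is lossless, so the modulation
        # vector must equal the vector FEM applied to the channel values
        fem = FEMSpatial(8, 3, rng)
        fem.eval()
        v = rng.normal(size=(2, 8))
        x = Tensor(np.broadcast_to(v[:, :, None, None], (2, 8, 6, 6)).copy())
        scale = fem.channel_scale(x).data
        oracle = fem.fem(Tensor(v)).data
        assert np.allclose(scale, oracle, atol=1e-12)

    def test_zero_map_zero_affine_gives_zero(self, rng):
        fem = FEMSpatial(8, 3, rng)
        fem.zero_all_parameters()
        fem.eval()
        out = fem(Tensor(np.zeros((2, 8, 4, 4))))
        assert np.allclose(out.data, 0.0)


class TestCrossAttention:
    def test_rows_are_probability_vectors(self, rng):
        q = Tensor(rng.normal(size=(3, 12)))
        k = Tensor(rng.normal(size=(3, 12)))
        _, attn = cross_attention(q, k, tokens=4)
        assert np.allclose(attn.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_identical_key_tokens_give_uniform_attention(self, rng):
        # all K tokens equal -> constant logits -> uniform rows -> output is
        # the mean of V rows, i.e. the common token
        token = rng.normal(size=4)
        ctx = Tensor(np.tile(token, (2, 3)))  # 3 identical tokens of width 4
        q = Tensor(rng.normal(size=(2, 12)))
        out, attn = cross_attention(q, ctx, tokens=3)
        assert np.allclose(attn.data, 1.0 / 3.0, atol=1e-12)
        assert np.allclose(out.data, np.tile(token, (2, 3)), atol=1e-12)

    def test_matches_hand_rolled_oracle_t2_d2(self, rng):
        q = rng.normal(size=(1, 4))
        c = rng.normal(size=(1, 4))
        out, _ = cross_attention(Tensor(q), Tensor(c), tokens=2)
        # independent oracle: explicit softmax(QK^T/sqrt(2)) V
        Q, K = q.reshape(2, 2), c.reshape(2, 2)
        logits = Q @ K.T / math.sqrt(2)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        A = e / e.sum(axis=1, keepdims=True)
        expected = (A @ K).reshape(1, 4)
        assert np.allclose(out.data, expected, atol=1e-9)

    def test_indivisible_token_count_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_attention(
                Tensor(rng.normal(size=(1, 10))),
                Tensor(rng.normal(size=(1, 10))),
                tokens=4,
            )


class TestFIM:
    def test_output_length_preserved(self, rng):
        fim = FIM(12, 4, rng)
        out = fim(Tensor(rng.normal(size=(3, 12))), Tensor(rng.normal(size=(3, 12))))
        assert out.shape == (3, 12)

    def test_zeroed_fc_reduces_to_residual_identity(self, rng):
        fim = FIM(12, 4, rng)
        fim.fc.weight.data[...] = 0.0
        fim.fc.bias.data[...] = 0.0
        fim.bn_post.gamma.data[...] = 0.0
        fim.bn_post.beta.data[...] = 0.0
        fim.eval()
        own = Tensor(rng.normal(size=(3, 12)))
        out = fim(own, Tensor(rng.normal(size=(3, 12))))
        assert np.allclose(out.data, own.data, atol=1e-12)

    def test_other_branch_receives_gradient(self, rng):
        # information must flow across branches: d loss / d other != 0
        fim = FIM(8, 2, rng)
        own = Tensor(rng.normal(size=(2, 8)), requires_grad=True)
        other = Tensor(rng.normal(size=(2, 8)), requires_grad=True)
        out = fim(own, other)
        (out * out).sum().backward()  # nonlinear loss: BN makes plain sums constant
        assert other.grad is not None and np.abs(other.grad).max() > 1e-8

    def test_generic_init_changes_feature(self, rng):
        fim = FIM(8, 2, rng)
        fim.eval()
        own = Tensor(rng.normal(size=(2, 8)))
        out = fim(own, Tensor(rng.normal(size=(2, 8))))
        assert not np.allclose(out.data, own.data)


class TestMLFM:
    @pytest.mark.parametrize("use_fem,use_fim", [(True, True), (True, False),
                                                 (False, True), (False, False)])
    def test_shapes_preserved_under_all_toggles(self, rng, use_fem, use_fim):
        mlfm = MLFM(8, 3, 4, rng, use_fem=use_fem, use_fim=use_fim)
        f = Tensor(rng.normal(size=(2, 8)))
        c = Tensor(rng.normal(size=(2, 8, 5, 5)))
        f_l, f_c = mlfm(f, c)
        assert f_l.shape == f.shape
        assert f_c.shape == c.shape

    def test_disabled_modules_pass_inputs_to_reduction(self, rng):
        # with FEM and FIM off, the vector path reduces concat(F, F)
        mlfm = MLFM(6, 3, 3, rng, use_fem=False, use_fim=False)
        f = Tensor(rng.normal(size=(2, 6)))
        c = Tensor(rng.normal(size=(2, 6, 4, 4)))
        f_l, _ = mlfm(f, c)
        w, b = mlfm.reduce_l.weight.data, mlfm.reduce_l.bias.data
        expected = np.concatenate([f.data, f.data], axis=1) @ w + b
        assert np.allclose(f_l.data, expected, atol=1e-10)

    def test_call_counter_increments(self, rng):
        mlfm = MLFM(6, 3, 3, rng)
        f = Tensor(rng.normal(size=(1, 6)))
        c = Tensor(rng.normal(size=(1, 6, 4, 4)))
        mlfm(f, c)
        mlfm(f, c)
        assert mlfm.n_calls == 2
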