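"""Peripheral-vision assistant: quadrants, attention, masked conv, interaction."""

import numpy as np
import pytest

from segdistill.assistant import (
    AssistantNet,
    MpaConv,
    MultiheadSelfAttention2d,
    PeripheralVisionBlock,
    RegionInteraction,
    partition_quadrants,
    reassemble_quadrants,
)
from segdistill.nn import SGD, Tensor, conv2d
from segdistill.teacher import SegmentationOutput, task_loss

from .oracles import attention_1head_loops, conv2d_loops, mpa_effective_kernel, region_interaction_script


class TestQuadrants:
    def test_160_gives_four_80s(self, rng):
        quads = partition_quadrants(Tensor(rng.normal(size=(1, 2, 160, 160))))
        assert all(q.shape == (1, 2, 80, 80) for q in quads)

    def test_reassemble_is_exact_inverse(self, rng):
        x = rng.normal(size=(2, 3, 10, 14)).astype(np.float32)
        quads = partition_quadrants(Tensor(x))
        np.testing.assert_array_equal(reassemble_quadrants(*quads).data, x)

    def test_two_by_two_matches_direct_indexing(self):
        x = np.arange(4, dtype=np.float32).reshape(1, 1, 2, 2)
        fa, fb, fc, fd = partition_quadrants(Tensor(x))
        assert (fa.data.item(), fb.data.item(), fc.data.item(), fd.data.item()) == (0, 1, 2, 3)

    def test_odd_dims_rejected(self, rng):
        with pytest.raises(ValueError):
            partition_quadrants(Tensor(rng.normal(size=(1, 1, 5, 4))))


class TestMultiheadAttention:
    def test_channels_must_divide_heads(self):
        with pytest.raises(ValueError):
            MultiheadSelfAttention2d(6, 4, np.random.default_rng(0))

    def test_single_token_attends_to_itself(self, rng):
        msa = MultiheadSelfAttention2d(4, 2, np.random.default_rng(1))
        x = rng.normal(size=(1, 4, 1, 1)).astype(np.float32)
        out = msa(Tensor(x))
        tok = x[0, :, 0, 0]
        expected = (tok @ msa.wv.weight.data) @ msa.wout.weight.data + msa.wout.bias.data
        np.testing.assert_allclose(out.data[0, :, 0, 0], expected, atol=1e-5)

    def test_attention_rows_are_stochastic(self, rng):
        msa = MultiheadSelfAttention2d(8, 2, np.random.default_rng(2))
        tokens = Tensor(rng.normal(size=(2, 9, 8)).astype(np.float32))
        attn = msa.attention_weights(tokens).data
        assert attn.min() >= 0
        np.testing.assert_allclose(attn.sum(axis=-1), 1.0, atol=1e-5)

    def test_three_token_single_head_matches_scalar_oracle(self, rng):
        msa = MultiheadSelfAttention2d(4, 1, np.random.default_rng(3))
        x = rng.normal(size=(1, 4, 1, 3)).astype(np.float32)  # 3 tokens
        out = msa(Tensor(x))
        tokens = x[0, :, 0, :].T  # (3, 4)
        ref = attention_1head_loops(
            tokens.astype(np.float64),
            msa.wq.weight.data, msa.wk.weight.data, msa.wv.weight.data,
            msa.wout.weight.data, msa.wout.bias.data,
            scale=1.0 / np.sqrt(4),
        )
        np.testing.assert_allclose(out.data[0, :, 0, :].T, ref, atol=1e-5)


class TestMpaConv:
    def test_theta_zero_reduces_to_plain_convolution(self, rng):
        mpa = MpaConv(3, 2, np.random.default_rng(4))
        mpa.theta.data = np.float32(0.0)
        x = Tensor(rng.normal(size=(2, 3, 6, 6)).astype(np.float32))
        plain = conv2d(x, mpa.weight, mpa.bias, padding=1)
        np.testing.assert_array_equal(mpa(x).data, plain.data)

    def test_zero_input_no_bias_gives_zero(self, rng):
        mpa = MpaConv(2, 2, np.random.default_rng(5))
        mpa.bias.data[:] = 0
        mpa.theta.data = np.float32(0.7)
        out = mpa(Tensor(np.zeros((1, 2, 4, 4), dtype=np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_center_mask_structure(self):
        mpa = MpaConv(1, 1, np.random.default_rng(6))
        assert mpa.center_mask[1, 1] == 1.0
        off = mpa.center_mask.copy()
        off[1, 1] = 0.5
        assert np.all(off == 0.5)

    def test_mask_initialized_uniform_pm1(self):
        draws = np.concatenate(
            [MpaConv(1, 1, np.random.default_rng(s)).mask_learn.data.ravel() for s in range(40)]
        )
        assert draws.min() >= -1.0 and draws.max() <= 1.0
        assert draws.min() < -0.8 and draws.max() > 0.8  # spans the interval

    def test_masked_convolution_matches_explicit_arithmetic(self, rng):
        mpa = MpaConv(2, 3, np.random.default_rng(7))
        mpa.theta.data = np.float32(0.31)
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        keff = mpa_effective_kernel(
            mpa.weight.data.astype(np.float64), mpa.mask_learn.data.astype(np.float64),
            float(mpa.theta.data),
        )
        ref = conv2d_loops(x, keff, mpa.bias.data, padding=1)
        np.testing.assert_allclose(mpa(Tensor(x)).data, ref, atol=1e-5)

    def test_mask_and_theta_receive_gradients(self, rng):
        mpa = MpaConv(2, 2, np.random.default_rng(8))
        mpa.theta.data = np.float32(0.2)
        x = Tensor(rng.normal(size=(2, 2, 6, 6)).astype(np.float32))
        (mpa(x) ** 2.0).sum().backward()
        assert np.abs(mpa.mask_learn.grad).max() > 0
        assert abs(float(mpa.theta.grad)) > 0


class TestRegionInteraction:
    def test_identical_quadrants_stay_identical_under_symmetric_weights(self, rng):
        """Region symmetry: if the mixing convs treat the four regions the
        same way (weight blocks shared across regions), identical inputs map
        to identical updated regions."""
        ri = RegionInteraction(4, np.random.default_rng(9))
        C = 4
        w = ri.conv1.weight.data
        for g in range(1, 4):  # share output blocks
            w[g * C : (g + 1) * C] = w[:C]
        for g in range(1, 4):  # make each block symmetric over input regions
            w[:, g * C : (g + 1) * C] = w[:, :C]
            for gg in range(4):
                w[gg * C : (gg + 1) * C, g * C : (g + 1) * C] = w[:C, :C]
        ri.conv1.bias.data[C:] = np.tile(ri.conv1.bias.data[:C], 3)
        # center-tap-only interaction conv: removes the seam dependence the
        # reassembled map introduces at internal quadrant borders
        center_only = np.zeros_like(ri.conv2.weight.data)
        center_only[:, :, 1, 1] = ri.conv2.weight.data[:, :, 1, 1]
        ri.conv2.weight.data = center_only
        q = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        outs = ri(q, q, q, q)
        for o in outs[1:]:
            np.testing.assert_allclose(o.data, outs[0].data, atol=1e-5)

    def test_zero_interaction_reduces_to_channel_softmax(self, rng):
        from segdistill import nn

        ri = RegionInteraction(4, np.random.default_rng(10))
        # force the sigmoid branch to ~0
        ri.conv2.weight.data[:] = 0
        ri.conv2.bias.data[:] = -60.0
        q = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        outs = ri(q, q, q, q)
        np.testing.assert_allclose(outs[0].data, nn.softmax(q, axis=1).data, atol=1e-4)

    def test_matches_scripted_operator_chain(self, rng):
        ri = RegionInteraction(4, np.random.default_rng(11))
        quads = [rng.normal(size=(1, 4, 4, 4)).astype(np.float32) for _ in range(4)]
        outs = ri(*[Tensor(q) for q in quads])
        ref = region_interaction_script(
            quads, ri.conv1.weight.data, ri.conv1.bias.data,
            ri.conv2.weight.data, ri.conv2.bias.data,
        )
        for o, r in zip(outs, ref):
            np.testing.assert_allclose(o.data, r, atol=1e-5)

    def test_mismatched_quadrants_rejected(self, rng):
        ri = RegionInteraction(4, np.random.default_rng(12))
        q = Tensor(rng.normal(size=(1, 4, 4, 4)).astype(np.float32))
        bad = Tensor(rng.normal(size=(1, 4, 2, 2)).astype(np.float32))
        with pytest.raises(ValueError):
            ri(q, q, q, bad)


class TestAssistantNet:
    def test_full_resolution_four_class_logits(self, rng):
        net = AssistantNet(np.random.default_rng(13), base_channels=4)
        x = Tensor(rng.uniform(0, 1, size=(1, 1, 64, 64)).astype(np.float32))
        assert net(x).logits.shape == (1, 4, 64, 64)

    def test_multichannel_input_rejected(self, rng):
        net = AssistantNet(np.random.default_rng(14), base_channels=4)
        with pytest.raises(ValueError):
            net(Tensor(rng.uniform(size=(1, 2, 64, 64)).astype(np.float32)))

    def test_loss_is_shared_with_teacher_task_loss(self, rng):
        """The assistant trains with the same CE+Dice objective as the teacher."""
        logits = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        label = rng.choice([0, 1, 2, 4], size=(1, 8, 8))
        a = task_loss(SegmentationOutput(logits), label)
        b = task_loss(SegmentationOutput(Tensor(logits.data.copy())), label)
        np.testing.assert_allclose(a.total.item(), b.total.item(), rtol=1e-7)

    def test_training_step_reaches_mask_and_theta(self, rng):
        net = AssistantNet(np.random.default_rng(15), base_channels=4)
        x = Tensor(rng.uniform(0, 1, size=(2, 1, 32, 32)).astype(np.float32))
        label = rng.choice([0, 1, 2, 4], size=(2, 32, 32))
        opt = SGD(net.parameters(), lr=0.1)
        before_mask = net.pv.mpa.mask_learn.data.copy()
        loss = task_loss(net(x), label).total
        opt.zero_grad()
        loss.backward()
        assert abs(float(net.pv.mpa.theta.grad)) > 0
        assert np.abs(net.pv.mpa.mask_learn.grad).max() > 0
        opt.step()
        assert not np.array_equal(net.pv.mpa.mask_learn.data, before_mask)


class TestPeripheralVisionBlock:
    def test_output_shape_preserved(self, rng):
        pv = PeripheralVisionBlock(4, 2, np.random.default_rng(16))
        x = Tensor(rng.normal(size=(1, 4, 8, 8)).astype(np.float32))
        assert pv(x).shape == (1, 4, 8, 8)
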