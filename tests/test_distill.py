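"""Distillation objective: blending, KD, competitive terms, training wiring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segdistill.distill import (
    CompetitiveTerms,
    DistillConfig,
    competitive_loss,
    kd_loss,
    student_loss,
    teacher_assistant_output,
    total_loss,
    train_student,
)
from segdistill.nn import Tensor, parameter_checksum
from segdistill.teacher import SegmentationOutput

from .oracles import kd_loss_scalar


def seg_out(logits) -> SegmentationOutput:
    return SegmentationOutput(Tensor(np.asarray(logits, dtype=np.float32)))


class TestConfig:
    @pytest.mark.parametrize(
        "bad",
        [
            {"temperature": 0.0},
            {"alpha": 1.5},
            {"mu": -1.0},
            {"ta_weight": 1.2},
            {"lambda_comp": -0.1},
        ],
    )
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            DistillConfig(**bad).validate()


class TestTeacherAssistantBlend:
    def test_weight_one_returns_teacher_probabilities(self, rng):
        t = seg_out(rng.normal(size=(2, 4, 4, 4)))
        a = seg_out(rng.normal(size=(2, 4, 4, 4)))
        blended = teacher_assistant_output(t, a, ta_weight=1.0)
        np.testing.assert_allclose(
            blended.probabilities.data, t.probabilities.data, atol=1e-5
        )

    def test_identical_inputs_are_fixed_point(self, rng):
        z = rng.normal(size=(1, 4, 3, 3))
        blended = teacher_assistant_output(seg_out(z), seg_out(z.copy()), ta_weight=0.5)
        np.testing.assert_allclose(
            blended.probabilities.data, seg_out(z).probabilities.data, atol=1e-5
        )

    def test_blend_renormalizes_classes(self, rng):
        t = seg_out(rng.normal(size=(3, 4, 5, 5)))
        a = seg_out(rng.normal(size=(3, 4, 5, 5)))
        blended = teacher_assistant_output(t, a, ta_weight=0.3)
        np.testing.assert_allclose(blended.probabilities.data.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            teacher_assistant_output(
                seg_out(rng.normal(size=(1, 4, 4, 4))),
                seg_out(rng.normal(size=(1, 4, 2, 2))),
                0.5,
            )


class TestKdLoss:
    def test_identical_logits_give_zero(self, rng):
        z = rng.normal(size=(2, 4, 4, 4))
        assert kd_loss(seg_out(z), seg_out(z.copy()), temperature=4.0).item() == 0.0

    def test_huge_temperature_softens_to_uniform(self, rng):
        a = seg_out(rng.normal(size=(1, 4, 3, 3)))
        b = seg_out(rng.normal(size=(1, 4, 3, 3)))
        assert kd_loss(a, b, temperature=1e6).item() < 1e-9

    def test_matches_scalar_oracle_on_single_pixel(self):
        zt = np.array([1.0, -0.5, 2.0])
        zs = np.array([0.2, 0.8, -1.0])
        out = kd_loss(
            seg_out(zt.reshape(1, 3, 1, 1)), seg_out(zs.reshape(1, 3, 1, 1)), temperature=2.0
        )
        # note the argument order (student, target) does not matter for the distance
        np.testing.assert_allclose(out.item(), kd_loss_scalar(zt, zs, 2.0), atol=1e-6)

    def test_nonpositive_temperature_rejected(self, rng):
        z = seg_out(rng.normal(size=(1, 4, 2, 2)))
        with pytest.raises(ValueError):
            kd_loss(z, z, temperature=0.0)


class TestStudentLoss:
    @pytest.mark.parametrize(
        "alpha,task,kd,expected", [(1.0, 2.0, 5.0, 2.0), (0.0, 2.0, 5.0, 5.0), (0.3, 2.0, 1.0, 1.3)]
    )
    def test_convex_combination(self, alpha, task, kd, expected):
        np.testing.assert_allclose(student_loss(task, kd, alpha), expected, rtol=1e-7)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            student_loss(1.0, 1.0, alpha=1.1)


class TestCompetitiveLoss:
    def test_tie_gives_exact_zero(self):
        losses = [0.4, 0.7, 1.2]
        value, terms = competitive_loss(losses, losses, losses)
        assert value == 0.0
        np.testing.assert_array_equal(terms.reward, 0.0)

    def test_published_scale_worked_example(self):
        """Single sample with L_T = L_TA = 0.5, L_S = 0.3 at the published
        reward scale 0.1 and difficulty scale 10."""
        value, terms = competitive_loss([0.5], [0.5], [0.3], lambda_reward=0.1, mu=10.0)
        np.testing.assert_allclose(terms.reward, [0.02], rtol=1e-12)
        np.testing.assert_allclose(terms.gamma, [0.625], rtol=1e-12)
        np.testing.assert_allclose(terms.delta, [np.exp(0.05)], rtol=1e-12)
        np.testing.assert_allclose(value, 0.625 * np.exp(0.05) * 0.02, rtol=1e-12)

    def test_sign_follows_weighted_reward(self, rng):
        lt = rng.uniform(0.1, 2.0, size=20)
        lta = rng.uniform(0.1, 2.0, size=20)
        ls = rng.uniform(0.1, 2.0, size=20)
        value, terms = competitive_loss(lt, lta, ls)
        weighted = terms.gamma * terms.delta * terms.reward
        assert np.sign(value) == np.sign(weighted.sum())

    def test_reward_slope_in_student_loss_is_minus_lambda(self):
        eps = 1e-6
        _, t1 = competitive_loss([1.0], [1.0], [0.5], lambda_reward=0.1)
        _, t2 = competitive_loss([1.0], [1.0], [0.5 + eps], lambda_reward=0.1)
        np.testing.assert_allclose((t2.reward[0] - t1.reward[0]) / eps, -0.1, rtol=1e-4)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.tuples(
            st.floats(0.01, 5.0), st.floats(0.0, 5.0), st.floats(0.01, 5.0)
        ), min_size=1, max_size=8)
    )
    def test_weight_ranges_hold_for_nonnegative_losses(self, triples):
        lt = [t[0] for t in triples]
        lta = [t[1] for t in triples]
        ls = [t[2] for t in triples]
        _, terms = competitive_loss(lt, lta, ls, mu=10.0)
        assert np.all(terms.gamma > 0) and np.all(terms.gamma < 1)
        assert np.all(terms.delta >= 1.0)

    def test_gamma_monotone_in_teacher_and_student_losses(self):
        _, lo = competitive_loss([0.5], [0.5], [0.5])
        _, hi = competitive_loss([1.5], [0.5], [0.5])
        assert hi.gamma[0] > lo.gamma[0]  # harder for the teacher -> larger
        _, hi_s = competitive_loss([0.5], [0.5], [1.5])
        assert hi_s.gamma[0] < lo.gamma[0]  # harder for the student -> smaller

    def test_negative_losses_rejected(self):
        with pytest.raises(ValueError):
            competitive_loss([0.5], [-0.1], [0.5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            competitive_loss([0.5], [0.5, 0.6], [0.5])


class TestTotalLoss:
    def test_weighted_sum_cases(self):
        zero = DistillConfig(lambda_student=0.0, lambda_comp=0.0, lambda_res=0.0)
        assert total_loss(2.0, 0.4, 1.0, zero) == 0.0
        only_student = DistillConfig(lambda_student=1.0, lambda_comp=0.0, lambda_res=0.0)
        assert total_loss(2.0, 0.4, 1.0, only_student) == 2.0
        mix = DistillConfig(lambda_student=1.0, lambda_comp=0.5, lambda_res=0.5)
        np.testing.assert_allclose(total_loss(2.0, 0.4, 1.0, mix), 2.7, rtol=1e-7)


@pytest.fixture(scope="module")
def frozen_teacher(tiny_phantoms):
    from segdistill.teacher import pretrain_teacher

    return pretrain_teacher(
        tiny_phantoms[:6], epochs=3, rng=np.random.default_rng(0),
        base_channels=4, mhmoe_heads=2, mhmoe_experts=2, batch_size=6,
    ).model


class TestTrainStudent:

    def test_teacher_checksum_unchanged_by_training(self, tiny_phantoms, frozen_teacher):
        before = parameter_checksum(frozen_teacher)
        train_student(
            tiny_phantoms[:6], "t1", frozen_teacher, DistillConfig(), epochs=2,
            rng=np.random.default_rng(1), base_channels=4, batch_size=6,
        )
        assert parameter_checksum(frozen_teacher) == before

    def test_component_toggles_zero_the_right_weights(self, tiny_phantoms, frozen_teacher):
        res = train_student(
            tiny_phantoms[:6], "t1", frozen_teacher, DistillConfig(), epochs=1,
            rng=np.random.default_rng(2), base_channels=4, batch_size=6,
            use_compete=False,
        )
        assert all(row["L_comp"] == 0.0 for row in res.log)
        res = train_student(
            tiny_phantoms[:6], "t1", frozen_teacher, DistillConfig(), epochs=1,
            rng=np.random.default_rng(2), base_channels=4, batch_size=6,
            use_assistant=False,
        )
        assert res.assistant is None
        assert all(row["L_assistant"] == 0.0 for row in res.log)
        res = train_student(
            tiny_phantoms[:6], "t1", frozen_teacher, DistillConfig(), epochs=1,
            rng=np.random.default_rng(2), base_channels=4, batch_size=6,
            use_kd=False, use_compete=False, use_assistant=False,
        )
        assert all(row["L_KD"] == 0.0 for row in res.log)
        np.testing.assert_allclose(
            [row["L_student"] for row in res.log], [row["L_task"] for row in res.log], rtol=1e-6
        )

    def test_log_contains_every_loss_component(self, tiny_phantoms, frozen_teacher):
        res = train_student(
            tiny_phantoms[:6], "t1", frozen_teacher, DistillConfig(), epochs=2,
            rng=np.random.default_rng(3), base_channels=4, batch_size=6,
            val_samples=tiny_phantoms[6:8], eval_every=2,
        )
        for key in ("L_task", "L_KD", "L_student", "L_comp", "L_assistant", "L_total"):
            assert key in res.log[0]
        assert "val_dice_wt" in res.log[-1]

    def test_unknown_modality_rejected(self, tiny_phantoms, frozen_teacher):
        with pytest.raises(ValueError):
            train_student(
                tiny_phantoms[:6], "dwi", frozen_teacher, DistillConfig(), epochs=1,
                rng=np.random.default_rng(4), base_channels=4,
            )

    def test_gradient_isolation_assistant_updates_teacher_does_not(
        self, tiny_phantoms, frozen_teacher
    ):
        from segdistill.assistant import AssistantNet

        assistant = AssistantNet(np.random.default_rng(5), base_channels=4)
        teacher_before = parameter_checksum(frozen_teacher)
        assistant_before = parameter_checksum(assistant)
        train_student(
            tiny_phantoms[:6], "t1", frozen_teacher, DistillConfig(), epochs=1,
            rng=np.random.default_rng(5), base_channels=4, batch_size=6,
            assistant=assistant, ema_decay=0.0,
        )
        assert parameter_checksum(frozen_teacher) == teacher_before
        assert parameter_checksum(assistant) != assistant_before
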