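"""Collaborative-competitive knowledge distillation.

Training proceeds in three steps: (1) pretrain the full-modality teacher and
freeze it; (2) distill knowledge into the single-modality student from the
teacher-assistant output (a convex blend of the frozen teacher's and the
trainable assistant's class probabilities) through a temperature-softened
soft-target loss; (3) add a competitive term built from per-sample rewards

    r_i     = lambda * (L_TA(x_i) - L_S(x_i))            (reward)
    gamma_i = L_T(x_i) / (L_T(x_i) + L_S(x_i))           (relative difficulty)
    delta_i = exp(L_TA(x_i) / mu)                        (emphasis)
    L_competitive = sum_i gamma_i * delta_i * r_i

where L_T, L_TA, L_S are the per-sample CE+Dice losses of the teacher, the
teacher-assistant blend, and the student.  The reward is positive exactly
when the student beats the teacher-assistant on a sample.  The training
objective *maximizes* the weighted reward (equivalently the negated reward
enters the total loss), which is what drives the student's loss below the
teacher-assistant's; the reported ``L_competitive`` follows the summed
gamma*delta*r form above.  Gradients never reach the teacher; they reach the
assistant through its own task loss and through the blended distillation
target.

Total objective:

    L_total = lambda_student * L_student
            + lambda_comp * (competitive term)
            + lambda_res * L_assistant
    with L_student = alpha * L_task + (1 - alpha) * L_KD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .assistant import AssistantNet
from .data import MultimodalSample
from .nn import Tensor
from .student import StudentNet, modality_batch
from .teacher import (
    SegmentationOutput,
    TeacherNet,
    batch_from_samples,
    task_loss,
    task_loss_per_sample,
)

__all__ = [
    "DistillConfig",
    "CompetitiveTerms",
    "LossBundle",
    "teacher_assistant_output",
    "kd_loss",
    "student_loss",
    "competitive_loss",
    "total_loss",
    "train_student",
    "StudentTrainResult",
]


@dataclass
class DistillConfig:
    """Hyperparameters of the distillation objective.

    lambda_reward = 0.1 and mu = 10 are the published reward/difficulty
    scales; temperature, alpha, the three total-loss weights and ta_weight
    are this package's defaults (the source leaves them unspecified) and are
    all configurable.  The defaults keep the absolute supervised signal
    equal to a task-only student's (lambda_student * alpha = 1) and treat
    the soft-target term as a mild regularizer (weight 1/4): the
    squared-probability distillation loss saturates where the student is
    confidently wrong, so a heavy weight mostly interferes with supervision
    rather than adding signal.  ta_weight = 1 makes the distillation target
    the teacher alone.
    """

    temperature: float = 4.0
    alpha: float = 0.8
    lambda_reward: float = 0.1
    mu: float = 10.0
    lambda_student: float = 1.25
    lambda_comp: float = 1.0
    lambda_res: float = 1.0
    ta_weight: float = 0.9

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if not 0.0 <= self.ta_weight <= 1.0:
            raise ValueError("ta_weight must lie in [0, 1]")
        for name in ("lambda_student", "lambda_comp", "lambda_res"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class CompetitiveTerms:
    reward: np.ndarray  # r_i
    gamma: np.ndarray  # relative difficulty in (0, 1)
    delta: np.ndarray  # emphasis >= 1 for nonnegative losses
    value: float  # sum_i gamma_i * delta_i * r_i


@dataclass
class LossBundle:
    task: float
    kd: float
    student: float
    competitive: float
    assistant: float
    total: float


def teacher_assistant_output(
    teacher_out: SegmentationOutput,
    assistant_out: SegmentationOutput,
    ta_weight: float,
) -> SegmentationOutput:
    """Blend teacher and assistant class probabilities.

    Returns an output whose logits are the log of the renormalized convex
    blend ta_weight * p_teacher + (1 - ta_weight) * p_assistant, so
    downstream softmax recovers the blended probabilities.
    """
    if teacher_out.logits.shape != assistant_out.logits.shape:
        raise ValueError("teacher/assistant output shapes disagree")
    if not 0.0 <= ta_weight <= 1.0:
        raise ValueError("ta_weight must lie in [0, 1]")
    pt = teacher_out.probabilities
    pa = assistant_out.probabilities
    blend = ta_weight * pt + (1.0 - ta_weight) * pa
    blend = blend / blend.sum(axis=1, keepdims=True)
    return SegmentationOutput((blend + 1e-12).log())


def kd_loss(
    student_out: SegmentationOutput, target_out: SegmentationOutput, temperature: float
) -> Tensor:
    """Squared L2 distance between temperature-softened softmax outputs.

    Mean over samples and pixels of the squared class-probability distance
    ||softmax(z_T / tau) - softmax(z_S / tau)||^2.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    ps = nn.softmax(student_out.logits * (1.0 / temperature), axis=1)
    pt = nn.softmax(target_out.logits * (1.0 / temperature), axis=1)
    diff = ps - pt
    B = diff.shape[0]
    hw = diff.shape[2] * diff.shape[3]
    return (diff**2.0).sum() * (1.0 / (B * hw))


def student_loss(task: Tensor | float, kd: Tensor | float, alpha: float):
    """Convex combination alpha * L_task + (1 - alpha) * L_KD."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * task + (1.0 - alpha) * kd


def competitive_loss(
    teacher_losses,
    teacher_assistant_losses,
    student_losses,
    lambda_reward: float = 0.1,
    mu: float = 10.0,
) -> tuple[float, CompetitiveTerms]:
    """Reward-weighted competitive loss over per-sample task losses.

    All three inputs are sequences of nonnegative per-sample CE+Dice losses:
    raw teacher (L_T), teacher-assistant blend (L_TA), student (L_S).
    Returns (value, per-sample terms) with value = sum_i gamma_i delta_i r_i.
    """
    lt = np.asarray(teacher_losses, dtype=np.float64)
    lta = np.asarray(teacher_assistant_losses, dtype=np.float64)
    ls = np.asarray(student_losses, dtype=np.float64)
    if not (lt.shape == lta.shape == ls.shape):
        raise ValueError("per-sample loss lists must have equal length")
    if (lt < 0).any() or (lta < 0).any() or (ls < 0).any():
        raise ValueError("per-sample losses must be nonnegative")
    reward = lambda_reward * (lta - ls)
    gamma = lt / (lt + ls)
    delta = np.exp(lta / mu)
    value = float((gamma * delta * reward).sum())
    return value, CompetitiveTerms(reward=reward, gamma=gamma, delta=delta, value=value)


def total_loss(
    student: Tensor | float,
    competitive: Tensor | float,
    assistant: Tensor | float,
    config: DistillConfig,
):
    """Weighted sum lambda_student*L_student + lambda_comp*L_comp + lambda_res*L_assistant."""
    return (
        config.lambda_student * student
        + config.lambda_comp * competitive
        + config.lambda_res * assistant
    )


def labels_all_for(dataset: list[MultimodalSample], idxs) -> np.ndarray:
    return np.stack([dataset[i].label for i in idxs])


@dataclass
class StudentTrainResult:
    student: StudentNet
    assistant: AssistantNet | None
    log: list[dict] = field(default_factory=list)

    def column(self, key: str) -> list[float]:
        return [row[key] for row in self.log]


def train_student(
    dataset: list[MultimodalSample],
    modality: str,
    frozen_teacher: TeacherNet | None,
    config: DistillConfig,
    epochs: int,
    rng: np.random.Generator | None = None,
    assistant: AssistantNet | None = None,
    student: StudentNet | None = None,
    base_channels: int = 8,
    assistant_channels: int | None = None,
    lr: float = 0.05,
    momentum: float = 0.9,
    weight_decay: float = 1.0e-4,
    batch_size: int | None = None,
    poly_power: float = 0.9,
    use_assistant: bool = True,
    use_kd: bool = True,
    use_compete: bool = True,
    ema_decay: float = 0.98,
    val_samples: list[MultimodalSample] | None = None,
    eval_every: int = 0,
) -> StudentTrainResult:
    """Joint training of student (and assistant) against a frozen teacher.

    Component toggles mirror the framework's ablation grid: ``use_kd=False``
    sets alpha to 1 (pure supervision), ``use_compete=False`` zeroes the
    competitive weight, ``use_assistant=False`` zeroes the assistant weight
    and pins the distillation target to the teacher alone.  With all three
    off this is a plain supervised baseline student.
    """
    config.validate()
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(0) if rng is None else rng
    # batch order drawn from a stream fixed *before* any network init, so
    # ablation arms sharing `rng` see identical data ordering
    order_rng = np.random.default_rng(int(rng.integers(2**31)))

    cfg = DistillConfig(**vars(config))
    if not use_compete:
        cfg.lambda_comp = 0.0
    if not use_assistant:
        cfg.lambda_res = 0.0
        cfg.ta_weight = 1.0
    alpha = 1.0 if not use_kd else cfg.alpha

    distilling = (use_kd or use_compete) and frozen_teacher is not None
    if distilling and frozen_teacher is None:
        raise ValueError("distillation requires a frozen teacher")

    if student is None:
        student = StudentNet(rng, base_channels=base_channels)
    if assistant is None and use_assistant and distilling:
        # the assistant is wider than the student by default: it must model
        # structure the student cannot, and a weak assistant pollutes the
        # blended distillation target
        assistant = AssistantNet(rng, base_channels=assistant_channels or 2 * base_channels)
    trainable = list(student.parameters())
    if assistant is not None and use_assistant and distilling:
        trainable += assistant.parameters()

    n = len(dataset)
    bs = n if batch_size is None else min(batch_size, n)
    opt = nn.SGD(
        trainable, lr=lr, momentum=momentum, weight_decay=weight_decay, max_grad_norm=10.0
    )
    steps_per_epoch = (n + bs - 1) // bs
    sched = nn.PolyLR(opt, max_iter=epochs * steps_per_epoch, power=poly_power)
    total_steps = epochs * steps_per_epoch
    ema = (
        nn.EMA(trainable, ema_decay, start_step=int(0.6 * total_steps))
        if ema_decay > 0
        else None
    )

    # frozen teacher: outputs are constants -> compute once per sample
    teacher_logits: dict[int, np.ndarray] = {}
    teacher_ps_losses: dict[int, float] = {}
    if distilling:
        frozen_teacher.eval()
        for start in range(0, n, bs):
            chunk = list(range(start, min(start + bs, n)))
            pa, pb, _ = batch_from_samples([dataset[i] for i in chunk])
            out = frozen_teacher.forward(pa, pb)
            ps = task_loss_per_sample(out, labels_all_for(dataset, chunk)).data
            for k, idx in enumerate(chunk):
                teacher_logits[idx] = out.logits.data[k : k + 1].copy()
                teacher_ps_losses[idx] = float(ps[k])

    result = StudentTrainResult(student=student, assistant=assistant)
    labels_all = np.stack([s.label for s in dataset])

    for epoch in range(epochs):
        order = order_rng.permutation(n)
        sums = {k: 0.0 for k in ("task", "kd", "student", "competitive", "assistant", "total")}
        for start in range(0, n, bs):
            idxs = order[start : start + bs]
            batch = [dataset[i] for i in idxs]
            labels = labels_all[idxs]
            x = modality_batch(batch, modality)

            student.train()
            s_out = student(x)
            l_task_ps = task_loss_per_sample(s_out, labels)  # (B,) differentiable
            l_task = l_task_ps.mean()

            l_kd = Tensor(np.zeros(()))
            l_assist = Tensor(np.zeros(()))
            comp_value = 0.0
            comp_term = Tensor(np.zeros(()))
            if distilling:
                t_out = SegmentationOutput(
                    Tensor(np.concatenate([teacher_logits[i] for i in idxs]))
                )
                if assistant is not None and use_assistant:
                    assistant.train()
                    a_out = assistant(x)
                    ta_out = teacher_assistant_output(t_out, a_out, cfg.ta_weight)
                    l_assist = task_loss(a_out, labels).total
                else:
                    ta_out = t_out
                if use_kd:
                    l_kd = kd_loss(s_out, ta_out, cfg.temperature)
                if use_compete:
                    lt = np.array([teacher_ps_losses[i] for i in idxs])
                    lta = task_loss_per_sample(ta_out, labels).data.astype(np.float64)
                    ls_const = l_task_ps.data.astype(np.float64)
                    comp_value, terms = competitive_loss(
                        lt, lta, ls_const, cfg.lambda_reward, cfg.mu
                    )
                    # maximize the weighted reward: gradient flows through the
                    # student's per-sample losses only (L_TA, gamma, delta constant)
                    w = (terms.gamma * terms.delta * cfg.lambda_reward).astype(np.float32)
                    comp_term = (Tensor(w) * (l_task_ps - Tensor(lta.astype(np.float32)))).sum()

            l_student = student_loss(l_task, l_kd, alpha)
            l_total = total_loss(l_student, comp_term, l_assist, cfg)
            opt.zero_grad()
            l_total.backward()
            opt.step()
            sched.step()
            if ema is not None:
                ema.update()

            nb = len(idxs)
            sums["task"] += l_task.item() * nb
            sums["kd"] += l_kd.item() * nb
            sums["student"] += l_student.item() * nb
            sums["competitive"] += comp_value * nb
            sums["assistant"] += l_assist.item() * nb
            sums["total"] += l_total.item() * nb

        row = {"epoch": epoch}
        row.update(
            {
                "L_task": sums["task"] / n,
                "L_KD": sums["kd"] / n,
                "L_student": sums["student"] / n,
                "L_comp": sums["competitive"] / n,
                "L_assistant": sums["assistant"] / n,
                "L_total": sums["total"] / n,
            }
        )
        if val_samples and eval_every and (epoch + 1) % eval_every == 0:
            from .evaluation import evaluate_segmenter

            report = evaluate_segmenter(student, val_samples, modality)
            row.update(
                {
                    "val_dice_wt": report.wt,
                    "val_dice_tc": report.tc,
                    "val_dice_et": report.et,
                }
            )
        result.log.append(row)

    if ema is not None:
        ema.copy_to()
        batches = [
            modality_batch(dataset[i : i + bs], modality) for i in range(0, n, bs)
        ]
        nn.refresh_batchnorm(student, lambda b: student(b), batches)
        if assistant is not None and use_assistant and distilling:
            nn.refresh_batchnorm(assistant, lambda b: assistant(b), batches)
    student.eval()
    if assistant is not None:
        assistant.eval()
    return result
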