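"""Desk-scale experiment drivers.

These functions wire the full pipeline (phantom generation, teacher
pretraining, competitive distillation, Dice evaluation) into the two
experiments the package uses to demonstrate itself on a CPU in minutes:

* :func:`teacher_capacity_experiment` — the teacher memorizes a single
  repeated phantom (an optimization sanity check, not a generalization
  claim).
* :func:`distillation_benefit_experiment` — paired comparison, over several
  seeds, of a single-modality student trained with the full collaborative-
  competitive objective against an identically initialized task-loss-only
  student, reporting validation whole-tumor Dice for both arms.

Problem sizes (64x64 phantoms, channel width 4, 40 student epochs) are the
package's desk profile; the reference configuration with the published
hyperparameters lives in ``segdistill.config``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import MultimodalSample, PhantomConfig, generate_dataset, split_cases
from .distill import DistillConfig, train_student
from .evaluation import RegionReport, evaluate_segmenter, evaluate_teacher
from .teacher import TeacherNet, pretrain_teacher
from .nn import parameter_checksum

__all__ = [
    "desk_phantom_split",
    "train_desk_teacher",
    "teacher_capacity_experiment",
    "distillation_benefit_experiment",
    "DistillationBenefitResult",
    "ablation_grid",
]

_MOD = 2**31


def _derive_seed(master_seed: int, stream: int) -> int:
    return (1_000_003 * int(master_seed) + 7919 * int(stream) + 17) % _MOD


def desk_phantom_split(
    n_cases: int, config: PhantomConfig, data_seed: int
) -> tuple[list[MultimodalSample], list[MultimodalSample], list[MultimodalSample]]:
    """Generate phantoms and split them 80/10/10 by case id."""
    samples = generate_dataset(n_cases, config, base_seed=data_seed)
    by_id = {s.case_id: s for s in samples}
    split = split_cases(sorted(by_id), seed=data_seed)
    return (
        [by_id[c] for c in split.train],
        [by_id[c] for c in split.val],
        [by_id[c] for c in split.test],
    )


def train_desk_teacher(
    train_samples: list[MultimodalSample],
    seed: int,
    epochs: int = 120,
    base_channels: int = 4,
    mhmoe_heads: int = 2,
    mhmoe_experts: int = 2,
    lr: float = 0.05,
    batch_size: int = 8,
    use_mhmoe: bool = True,
) -> TeacherNet:
    """Pretrain and freeze a desk-profile teacher."""
    res = pretrain_teacher(
        train_samples,
        epochs=epochs,
        rng=np.random.default_rng(_derive_seed(seed, 1)),
        base_channels=base_channels,
        mhmoe_heads=mhmoe_heads,
        mhmoe_experts=mhmoe_experts,
        use_mhmoe=use_mhmoe,
        lr=lr,
        batch_size=batch_size,
    )
    return res.model


def teacher_capacity_experiment(seed: int = 0, steps: int = 200, image_size: int = 64) -> dict:
    """Overfit the teacher to one repeated phantom; report training WT Dice.

    A capacity/optimization check: with a single sample the teacher should
    drive whole-tumor Dice above 0.9 within a couple hundred gradient steps.
    """
    cfg = PhantomConfig.desk(image_size)
    sample = generate_dataset(1, cfg, base_seed=_derive_seed(seed, 2))[0]
    res = pretrain_teacher(
        [sample],
        epochs=steps,  # one sample -> one step per epoch
        rng=np.random.default_rng(_derive_seed(seed, 3)),
        base_channels=4,
        mhmoe_heads=2,
        mhmoe_experts=2,
        lr=0.05,
        ema_decay=0.0,
        freeze=False,
    )
    res.model.eval()
    report = evaluate_teacher(res.model, [sample])
    return {
        "wt_dice": report.wt,
        "tc_dice": report.tc,
        "et_dice": report.et,
        "steps": steps,
        "final_loss": res.losses[-1],
    }


@dataclass
class DistillationBenefitResult:
    teacher_report: RegionReport
    per_seed: list[dict] = field(default_factory=list)

    @property
    def wins(self) -> int:
        return sum(1 for r in self.per_seed if r["full_wt"] > r["baseline_wt"])

    @property
    def win_fraction(self) -> float:
        return self.wins / len(self.per_seed)

    @property
    def mean_full_wt(self) -> float:
        return float(np.mean([r["full_wt"] for r in self.per_seed]))

    @property
    def mean_baseline_wt(self) -> float:
        return float(np.mean([r["baseline_wt"] for r in self.per_seed]))

    @property
    def mean_delta_wt(self) -> float:
        return self.mean_full_wt - self.mean_baseline_wt


def distillation_benefit_experiment(
    master_seed: int = 0,
    seeds: list[int] | None = None,
    n_cases: int = 30,
    image_size: int = 64,
    modality: str = "t1",
    student_epochs: int = 40,
    teacher_epochs: int = 120,
    base_channels: int = 4,
    distill_config: DistillConfig | None = None,
    verify_freeze: bool = True,
) -> DistillationBenefitResult:
    """Paired full-objective vs task-only student comparison.

    One frozen teacher is pretrained on its own phantom training set; each
    seed then draws a fresh 30-case phantom dataset (80/10/10 split) and
    trains two students from identical initializations: one with the full
    collaborative-competitive objective, one with the task loss alone.
    Reports per-seed validation whole-tumor Dice for both arms.
    """
    cfg = PhantomConfig.desk(image_size)
    dc = distill_config or DistillConfig()

    t_train, t_val, _ = desk_phantom_split(n_cases, cfg, _derive_seed(master_seed, 10))
    teacher = train_desk_teacher(
        t_train, master_seed, epochs=teacher_epochs, base_channels=base_channels
    )
    result = DistillationBenefitResult(teacher_report=evaluate_teacher(teacher, t_val))
    checksum_before = parameter_checksum(teacher)

    for s in seeds if seeds is not None else range(10):
        data_seed = _derive_seed(master_seed, 100 + s)
        train, val, _ = desk_phantom_split(n_cases, cfg, data_seed)
        full = train_student(
            train,
            modality,
            teacher,
            dc,
            epochs=student_epochs,
            rng=np.random.default_rng(s),
            base_channels=base_channels,
            lr=0.05,
            batch_size=8,
        )
        baseline = train_student(
            train,
            modality,
            None,
            dc,
            epochs=student_epochs,
            rng=np.random.default_rng(s),
            base_channels=base_channels,
            lr=0.05,
            batch_size=8,
            use_kd=False,
            use_compete=False,
            use_assistant=False,
        )
        result.per_seed.append(
            {
                "seed": s,
                "full_wt": evaluate_segmenter(full.student, val, modality).wt,
                "baseline_wt": evaluate_segmenter(baseline.student, val, modality).wt,
            }
        )
    if verify_freeze and parameter_checksum(teacher) != checksum_before:
        raise RuntimeError("frozen teacher parameters changed during student training")
    return result


def ablation_grid(
    master_seed: int = 0,
    seeds: list[int] | None = None,
    components: tuple[str, ...] = ("mhmoe", "assistant", "compete"),
    n_cases: int = 30,
    image_size: int = 64,
    modality: str = "t1",
    student_epochs: int = 40,
    teacher_epochs: int = 120,
    base_channels: int = 4,
) -> list[dict]:
    """Toggle framework components and report mean WT Dice deltas vs baseline.

    Rows mirror the framework's component-ablation table: each row enables a
    subset of {mhmoe, assistant, compete}; the delta is mean validation WT
    Dice (over seeds) minus the task-only baseline's.  Teachers are trained
    once per MHMoE setting; distillation arms share data and inits per seed.
    """
    from itertools import product

    cfg = PhantomConfig.desk(image_size)
    seeds = list(seeds) if seeds is not None else [0, 1, 2]
    t_train, _, _ = desk_phantom_split(n_cases, cfg, _derive_seed(master_seed, 10))
    teachers = {
        flag: train_desk_teacher(
            t_train,
            master_seed,
            epochs=teacher_epochs,
            base_channels=base_channels,
            use_mhmoe=flag,
        )
        for flag in {True, False}
    }
    datasets = {}
    for s in seeds:
        datasets[s] = desk_phantom_split(n_cases, cfg, _derive_seed(master_seed, 100 + s))

    def run(use_mhmoe: bool, use_assistant: bool, use_compete: bool, s: int) -> float:
        train, val, _ = datasets[s]
        r = train_student(
            train,
            modality,
            teachers[use_mhmoe],
            DistillConfig(),
            epochs=student_epochs,
            rng=np.random.default_rng(s),
            base_channels=base_channels,
            lr=0.05,
            batch_size=8,
            use_assistant=use_assistant,
            use_compete=use_compete,
        )
        return evaluate_segmenter(r.student, val, modality).wt

    base_by_seed = {}
    for s in seeds:
        train, val, _ = datasets[s]
        r = train_student(
            train,
            modality,
            None,
            DistillConfig(),
            epochs=student_epochs,
            rng=np.random.default_rng(s),
            base_channels=base_channels,
            lr=0.05,
            batch_size=8,
            use_kd=False,
            use_compete=False,
            use_assistant=False,
        )
        base_by_seed[s] = evaluate_segmenter(r.student, val, modality).wt

    rows = []
    for flags in product([True, False], repeat=len(components)):
        conf = dict(zip(components, flags))
        if not any(flags):
            continue
        wts = [
            run(conf.get("mhmoe", True), conf.get("assistant", True), conf.get("compete", True), s)
            for s in seeds
        ]
        rows.append(
            {
                **{c: conf[c] for c in components},
                "mean_wt": float(np.mean(wts)),
                "delta_wt_vs_baseline": float(np.mean(wts) - np.mean(list(base_by_seed.values()))),
            }
        )
    return rows
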