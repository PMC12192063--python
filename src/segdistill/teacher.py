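"""Full-modality teacher network and its supervised pretraining.

Pipeline: the two clinically complementary modality pairs (T1 || T1ce and
T2 || FLAIR) are channel-concatenated, lifted to the working width, fused by
content-guided attention, enhanced by the multihead mixture of experts, and
segmented by a 4-level U-Net into four classes (background,
necrotic/non-enhancing core, edema, enhancing tumor).

The task loss is pixelwise cross-entropy plus the sum over the three tumor
classes of (1 - soft Dice).  After pretraining the teacher is frozen: its
parameters take no further gradient updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .cgafusion import CGAFusion, PairStream
from .data import MultimodalSample
from .mhmoe import MHMoE, MhmoeConfig
from .nn import Tensor
from .unet import UNet

__all__ = [
    "LABEL_TO_CLASS",
    "CLASS_TO_LABEL",
    "SegmentationOutput",
    "TaskLoss",
    "TeacherNet",
    "task_loss",
    "task_loss_per_sample",
    "encode_labels",
    "batch_from_samples",
    "pretrain_teacher",
    "TrainResult",
]

LABEL_TO_CLASS = {0: 0, 1: 1, 2: 2, 4: 3}
CLASS_TO_LABEL = np.array([0, 1, 2, 4], dtype=np.int64)
NUM_CLASSES = 4
FOREGROUND_CLASSES = (1, 2, 3)


def encode_labels(label: np.ndarray) -> np.ndarray:
    """Map BraTS labels {0,1,2,4} to contiguous class indices {0,1,2,3}."""
    bad = set(np.unique(label)) - set(LABEL_TO_CLASS)
    if bad:
        raise ValueError(f"unknown label values {sorted(bad)}")
    out = label.copy()
    out[label == 4] = 3
    return out.astype(np.int64)


@dataclass
class SegmentationOutput:
    logits: Tensor  # (B, 4, H, W)

    @property
    def probabilities(self) -> Tensor:
        return nn.softmax(self.logits, axis=1)

    def predicted_labels(self) -> np.ndarray:
        """(B, H, W) argmax prediction mapped back to BraTS labels."""
        cls = self.logits.data.argmax(axis=1)
        return CLASS_TO_LABEL[cls]


@dataclass
class TaskLoss:
    ce: Tensor
    dice: Tensor

    @property
    def total(self) -> Tensor:
        return self.ce + self.dice


@dataclass
class TrainResult:
    model: "nn.Module"
    losses: list[float] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)


class TeacherNet(nn.Module):
    """Pair-fused, expert-enhanced U-Net segmenter over four modalities."""

    def __init__(
        self,
        rng: np.random.Generator,
        base_channels: int = 32,
        mhmoe_heads: int = 4,
        mhmoe_experts: int = 4,
        use_mhmoe: bool = True,
    ):
        super().__init__()
        self.base_channels = base_channels
        self.pair_a = PairStream(base_channels, rng)  # t1 || t1ce
        self.pair_b = PairStream(base_channels, rng)  # t2 || flair
        self.fusion = CGAFusion(base_channels, rng)
        self.use_mhmoe = use_mhmoe
        if use_mhmoe:
            self.mhmoe = MHMoE(
                MhmoeConfig(
                    num_heads=mhmoe_heads,
                    num_experts=mhmoe_experts,
                    channels=base_channels,
                ),
                rng,
            )
        self.unet = UNet(base_channels, NUM_CLASSES, base_channels, rng)

    def forward(self, pair_a: Tensor, pair_b: Tensor) -> SegmentationOutput:
        """pair_a: (B, 2, H, W) = t1||t1ce; pair_b: (B, 2, H, W) = t2||flair."""
        if pair_a.shape != pair_b.shape:
            raise ValueError("modality pair shapes disagree")
        fa = self.pair_a(pair_a)
        fb = self.pair_b(pair_b)
        fused = self.fusion(fa, fb)
        if self.use_mhmoe:
            fused = self.mhmoe(fused)
        return SegmentationOutput(self.unet(fused))

    def forward_samples(self, samples: list[MultimodalSample]) -> SegmentationOutput:
        pa, pb, _ = batch_from_samples(samples)
        return self.forward(pa, pb)


def batch_from_samples(
    samples: list[MultimodalSample],
) -> tuple[Tensor, Tensor, np.ndarray]:
    """Stack samples into the two pair tensors and the class-index target."""
    if not samples:
        raise ValueError("empty sample list")
    for s in samples:
        for m in ("t1", "t1ce", "t2", "flair"):
            if s.modality(m) is None:
                raise ValueError(f"teacher input requires all modalities; {m} missing")
    pa = np.stack([np.stack([s.t1, s.t1ce], axis=0) for s in samples]).astype(np.float32)
    pb = np.stack([np.stack([s.t2, s.flair], axis=0) for s in samples]).astype(np.float32)
    target = np.stack([encode_labels(s.label) for s in samples])
    return Tensor(pa), Tensor(pb), target


def task_loss(output: SegmentationOutput, label: np.ndarray, eps: float = 1e-5) -> TaskLoss:
    """Cross-entropy + summed soft-Dice loss over the tumor classes.

    `label` is a (B, H, W) or (H, W) BraTS label map (values in {0,1,2,4}).
    """
    if label.ndim == 2:
        label = label[None]
    target = encode_labels(label)
    ce = nn.cross_entropy(output.logits, target, reduction="mean")
    dice = nn.soft_dice_loss(
        output.probabilities, target, FOREGROUND_CLASSES, eps=eps, reduction="mean"
    )
    return TaskLoss(ce=ce, dice=dice)


def task_loss_per_sample(
    output: SegmentationOutput, label: np.ndarray, eps: float = 1e-5
) -> Tensor:
    """(B,) per-sample CE + Dice losses (used by the competitive objective)."""
    if label.ndim == 2:
        label = label[None]
    target = encode_labels(label)
    ce = nn.cross_entropy(output.logits, target, reduction="per_sample")
    dice = nn.soft_dice_loss(
        output.probabilities, target, FOREGROUND_CLASSES, eps=eps, reduction="per_sample"
    )
    return ce + dice


def pretrain_teacher(
    dataset: list[MultimodalSample],
    epochs: int,
    rng: np.random.Generator | None = None,
    base_channels: int = 8,
    mhmoe_heads: int = 4,
    mhmoe_experts: int = 4,
    use_mhmoe: bool = True,
    lr: float = 2.0e-4,
    momentum: float = 0.9,
    weight_decay: float = 1.0e-4,
    batch_size: int | None = None,
    poly_power: float = 0.9,
    freeze: bool = True,
    model: TeacherNet | None = None,
    ema_decay: float = 0.98,
) -> TrainResult:
    """Supervised pretraining of the teacher; parameters frozen afterwards.

    Uses SGD with momentum, weight decay and polynomial learning-rate decay.
    Returns the (frozen) model plus the per-epoch mean training loss.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(0) if rng is None else rng
    if model is None:
        model = TeacherNet(
            rng,
            base_channels=base_channels,
            mhmoe_heads=mhmoe_heads,
            mhmoe_experts=mhmoe_experts,
            use_mhmoe=use_mhmoe,
        )
    n = len(dataset)
    bs = n if batch_size is None else min(batch_size, n)
    opt = nn.SGD(
        model.parameters(), lr=lr, momentum=momentum, weight_decay=weight_decay,
        max_grad_norm=10.0,
    )
    steps_per_epoch = (n + bs - 1) // bs
    sched = nn.PolyLR(opt, max_iter=epochs * steps_per_epoch, power=poly_power)
    total_steps = epochs * steps_per_epoch
    ema = (
        nn.EMA(model.parameters(), ema_decay, start_step=int(0.6 * total_steps))
        if ema_decay > 0
        else None
    )
    result = TrainResult(model=model)
    model.train()
    for _epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            batch = [dataset[i] for i in order[start : start + bs]]
            pa, pb, target = batch_from_samples(batch)
            out = model.forward(pa, pb)
            loss = task_loss(out, CLASS_TO_LABEL[target]).total
            opt.zero_grad()
            loss.backward()
            opt.step()
            sched.step()
            if ema is not None:
                ema.update()
            epoch_loss += loss.item() * len(batch)
        result.losses.append(epoch_loss / n)
        result.log.append({"epoch": _epoch, "train_loss": result.losses[-1]})
    if ema is not None:
        ema.copy_to()

        def _fwd(batch):
            pa, pb, _ = batch_from_samples(batch)
            model.forward(pa, pb)

        batches = [dataset[i : i + bs] for i in range(0, n, bs)]
        nn.refresh_batchnorm(model, _fwd, batches)
    model.eval()
    if freeze:
        model.freeze()
    return result
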