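"""Multihead Mixture of convolutional Experts (MHMoE) feature enhancement.

Input channels are split into heads; each head owns an independent bank of
convolutional experts and a per-pixel gating network.  For head i with
features X_i, expert outputs E_j(X_i) are fused as

    O_i = sum_j G_{i,j} * E_j(X_i),      G_i = softmax(Gate(X_i))

where the gate produces one weight per expert per pixel (B x k x H x W),
soft-broadcast over the head's channels, and the head outputs are
re-concatenated in their original channel order.  Mixing is soft: every
expert stays active, weighted — there is no sparse top-m dispatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["MhmoeConfig", "ConvExpert", "MHMoE"]


@dataclass
class MhmoeConfig:
    num_heads: int = 4
    num_experts: int = 4
    channels: int = 32
    kernel_size: int = 3
    share_experts_across_heads: bool = False

    def validate(self) -> None:
        if self.num_heads < 1 or self.num_experts < 1:
            raise ValueError("num_heads and num_experts must be >= 1")
        if self.channels % self.num_heads:
            raise ValueError(
                f"channels ({self.channels}) not divisible by num_heads ({self.num_heads})"
            )


class ConvExpert(nn.Module):
    """Two consecutive 3x3 convolutions with one ReLU in between.

    Padding preserves the spatial shape; channel count is preserved.
    """

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, kernel_size, rng)
        self.conv2 = nn.Conv2d(channels, channels, kernel_size, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu())


class MHMoE(nn.Module):
    """Multihead mixture-of-experts layer; output shape equals input shape."""

    def __init__(self, config: MhmoeConfig, rng: np.random.Generator):
        super().__init__()
        config.validate()
        self.config = config
        ch_per_head = config.channels // config.num_heads
        self.ch_per_head = ch_per_head
        if config.share_experts_across_heads:
            shared = [
                ConvExpert(ch_per_head, config.kernel_size, rng)
                for _ in range(config.num_experts)
            ]
            self.experts = nn.ModuleList(
                [nn.ModuleList(shared) for _ in range(config.num_heads)]
            )
        else:
            self.experts = nn.ModuleList(
                [
                    nn.ModuleList(
                        [
                            ConvExpert(ch_per_head, config.kernel_size, rng)
                            for _ in range(config.num_experts)
                        ]
                    )
                    for _ in range(config.num_heads)
                ]
            )
        # gate: one 1x1 conv from head channels to k expert logits per pixel
        self.gates = nn.ModuleList(
            [
                nn.Conv2d(ch_per_head, config.num_experts, 1, rng)
                for _ in range(config.num_heads)
            ]
        )

    # -- exposed sub-operations (unit-testable) ---------------------------

    def head_slice(self, x: Tensor, head_index: int) -> Tensor:
        lo = head_index * self.ch_per_head
        return x[:, lo : lo + self.ch_per_head, :, :]

    def expert_forward(self, head_features: Tensor, head_index: int, expert_index: int) -> Tensor:
        if head_features.shape[1] != self.ch_per_head:
            raise ValueError(
                f"expected {self.ch_per_head} channels per head, got {head_features.shape[1]}"
            )
        return self.experts[head_index][expert_index](head_features)

    def gate_forward(self, head_features: Tensor, head_index: int) -> Tensor:
        """Per-pixel softmax weights over experts: (B, k, H, W), rows sum to 1."""
        logits = self.gates[head_index](head_features)
        return nn.softmax(logits, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        cfg = self.config
        if x.shape[1] != cfg.channels:
            raise ValueError(f"expected {cfg.channels} channels, got {x.shape[1]}")
        head_outputs = []
        for i in range(cfg.num_heads):
            xi = self.head_slice(x, i)
            gi = self.gate_forward(xi, i)  # (B, k, H, W)
            oi = None
            for j in range(cfg.num_experts):
                ej = self.expert_forward(xi, i, j)
                wij = gi[:, j : j + 1, :, :]  # broadcast over head channels
                term = ej * wij
                oi = term if oi is None else oi + term
            head_outputs.append(oi)
        return nn.concat(head_outputs, axis=1)
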