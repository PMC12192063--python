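"""Content-guided attention (CGA) fusion of two feature streams.

Channel weights Wc (global average pooling -> 1x1 conv -> ReLU -> 1x1 conv)
and spatial weights Ws (channel-mean and channel-max maps -> 7x7 conv) are
added into coarse weights Wcoa; Wcoa is interleaved with the shared input
x = fa + fb by a channel shuffle, refined by a 7x7 depthwise (group)
convolution and a sigmoid into final per-channel-per-pixel weights
Wfinal in (0, 1); the fused output is the gated blend

    out = Wfinal * fa + (1 - Wfinal) * fb,

so every output element lies between the corresponding elements of the two
inputs.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["channel_shuffle", "CGAFusion", "PairStream"]


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave channels of `groups` equal blocks: [a1..aC,b1..bC] -> [a1,b1,...]."""
    B, C, H, W = x.shape
    if C % groups:
        raise ValueError("channels not divisible by groups")
    return (
        x.reshape(B, groups, C // groups, H, W)
        .transpose(0, 2, 1, 3, 4)
        .reshape(B, C, H, W)
    )


class CGAFusion(nn.Module):
    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4):
        super().__init__()
        self.channels = channels
        hidden = max(1, channels // reduction)
        self.wc_fc1 = nn.Conv2d(channels, hidden, 1, rng)
        self.wc_fc2 = nn.Conv2d(hidden, channels, 1, rng)
        self.ws_conv = nn.Conv2d(2, 1, 7, rng)
        # refinement: shuffle(Wcoa, x) has 2C channels; depthwise 7x7 with
        # C groups maps each (weight, feature) pair to one channel weight
        self.refine = nn.Conv2d(2 * channels, channels, 7, rng, groups=channels)

    def channel_weights(self, x: Tensor) -> Tensor:
        """(B, C, 1, 1) channel attention from global average pooling."""
        pooled = x.mean(axis=(2, 3), keepdims=True)
        return self.wc_fc2(self.wc_fc1(pooled).relu())

    def spatial_weights(self, x: Tensor) -> Tensor:
        """(B, 1, H, W) spatial attention from channel mean/max maps."""
        mean_map = x.mean(axis=1, keepdims=True)
        max_map = _channel_max(x)
        return self.ws_conv(nn.concat([mean_map, max_map], axis=1))

    def coarse_weights(self, x: Tensor) -> Tensor:
        """Wcoa = broadcast(Wc) + broadcast(Ws), shape (B, C, H, W)."""
        wc = self.channel_weights(x)
        ws = self.spatial_weights(x)
        zeros = Tensor(np.zeros(x.shape, dtype=np.float32))
        return zeros + wc + ws  # explicit broadcast to B x C x H x W

    def final_weights(self, x: Tensor) -> Tensor:
        wcoa = self.coarse_weights(x)
        mixed = channel_shuffle(nn.concat([wcoa, x], axis=1), groups=2)
        return self.refine(mixed).sigmoid()

    def forward(self, fa: Tensor, fb: Tensor) -> Tensor:
        if fa.shape != fb.shape:
            raise ValueError(f"shape mismatch: {fa.shape} vs {fb.shape}")
        w = self.final_weights(fa + fb)
        return w * fa + (1.0 - w) * fb


def _channel_max(x: Tensor) -> Tensor:
    """Differentiable channel-axis max via one-hot argmax selection."""
    idx = x.data.argmax(axis=1, keepdims=True)
    onehot = np.zeros_like(x.data)
    np.put_along_axis(onehot, idx, 1.0, axis=1)
    return (x * Tensor(onehot)).sum(axis=1, keepdims=True)


class PairStream(nn.Module):
    """Lift one channel-concatenated modality pair to the working width."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(2, channels, 3, rng)

    def forward(self, pair: Tensor) -> Tensor:
        return self.conv(pair).relu()
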