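"""U-Net style encoder-decoder backbones.

``UNet`` is the 4-level teacher backbone (four 2x downsamplings, four 2x
upsamplings, skip connections between mirrored levels).  ``CompactEncoderDecoder``
is a 3-level variant of the same double-conv design used by the assistant
and student heads.  Each block is two 3x3 convolutions, each followed by
batch normalization and ReLU.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["DoubleConv", "UNet", "CompactEncoderDecoder"]


class DoubleConv(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = nn.BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).relu()
        return self.bn2(self.conv2(x)).relu()


class _EncoderDecoder(nn.Module):
    """Shared encoder-decoder machinery parameterized by depth."""

    def __init__(self, in_ch: int, num_classes: int, base: int, depth: int, rng):
        super().__init__()
        self.depth = depth
        widths = [base * (2**i) for i in range(depth + 1)]
        self.enc = nn.ModuleList()
        ch = in_ch
        for w in widths:
            self.enc.append(DoubleConv(ch, w, rng))
            ch = w
        self.up = nn.ModuleList()
        self.dec = nn.ModuleList()
        for i in range(depth, 0, -1):
            self.up.append(nn.Conv2d(widths[i], widths[i - 1], 1, rng))
            self.dec.append(DoubleConv(widths[i - 1] * 2, widths[i - 1], rng))
        self.head = nn.Conv2d(base, num_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        H, W = x.shape[2], x.shape[3]
        div = 2**self.depth
        if H % div or W % div:
            raise ValueError(
                f"spatial dims {(H, W)} must be divisible by {div} for depth {self.depth}"
            )
        skips = []
        for i, block in enumerate(self.enc):
            x = block(x)
            if i < self.depth:
                skips.append(x)
                x = nn.maxpool2x2(x)
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up(nn.upsample2x(x))
            x = dec(nn.concat([skip, x], axis=1))
        return self.head(x)


class UNet(_EncoderDecoder):
    """4-level U-Net: input must have H, W divisible by 16."""

    def __init__(self, in_ch: int, num_classes: int, base: int, rng: np.random.Generator):
        super().__init__(in_ch, num_classes, base, depth=4, rng=rng)


class CompactEncoderDecoder(_EncoderDecoder):
    """3-level encoder-decoder: input must have H, W divisible by 8."""

    def __init__(self, in_ch: int, num_classes: int, base: int, rng: np.random.Generator):
        super().__init__(in_ch, num_classes, base, depth=3, rng=rng)
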