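"""Peripheral-vision assistant network.

The assistant sees the same single modality as the student and supplies
structural knowledge that the frozen teacher cannot update.  Its core block
mimics human vision: the feature map is partitioned into four quadrants
(saccade-like region decomposition); each region passes through a standard
multihead self-attention branch (global content) and a mask-modulated MPA
convolution branch whose learnable kernel mask emphasizes the kernel center
(foveal weighting); the branches are combined and the four regions interact
through a convolutional mixing block before a compact encoder-decoder head
produces 4-class logits.  The assistant loss has the same CE + Dice form as
the teacher's.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor
from .teacher import NUM_CLASSES, SegmentationOutput
from .unet import CompactEncoderDecoder, DoubleConv

__all__ = [
    "partition_quadrants",
    "reassemble_quadrants",
    "MultiheadSelfAttention2d",
    "MpaConv",
    "RegionInteraction",
    "PeripheralVisionBlock",
    "AssistantNet",
]


def partition_quadrants(x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
    """Split (B, C, H, W) into four equal non-overlapping quadrants.

    Order: top-left, top-right, bottom-left, bottom-right.  H and W must be
    even; ``reassemble_quadrants`` is the exact inverse.
    """
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"quadrant partition requires even spatial dims, got {(H, W)}")
    h, w = H // 2, W // 2
    fa = x[:, :, :h, :w]
    fb = x[:, :, :h, w:]
    fc = x[:, :, h:, :w]
    fd = x[:, :, h:, w:]
    return fa, fb, fc, fd


def reassemble_quadrants(fa: Tensor, fb: Tensor, fc: Tensor, fd: Tensor) -> Tensor:
    top = nn.concat([fa, fb], axis=3)
    bottom = nn.concat([fc, fd], axis=3)
    return nn.concat([top, bottom], axis=2)


class MultiheadSelfAttention2d(nn.Module):
    """Standard multihead self-attention over pixels of a feature map.

    Each pixel is one token with the channel vector as its embedding.
    Attention logits are scaled by 1/sqrt(head_dim); rows of the attention
    matrix are nonnegative and sum to one.  Heads are concatenated and
    linearly projected with bias.
    """

    def __init__(self, channels: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if channels % num_heads:
            raise ValueError(
                f"channels ({channels}) not divisible by num_heads ({num_heads})"
            )
        self.channels = channels
        self.num_heads = num_heads
        self.head_dim = channels // num_heads
        self.wq = nn.Linear(channels, channels, rng, bias=False)
        self.wk = nn.Linear(channels, channels, rng, bias=False)
        self.wv = nn.Linear(channels, channels, rng, bias=False)
        self.wout = nn.Linear(channels, channels, rng, bias=True)

    def attention_weights(self, tokens: Tensor) -> Tensor:
        """(B, heads, N, N) row-stochastic attention matrix."""
        B, N, C = tokens.shape
        h, d = self.num_heads, self.head_dim
        q = self.wq(tokens).reshape(B, N, h, d).transpose(0, 2, 1, 3)
        k = self.wk(tokens).reshape(B, N, h, d).transpose(0, 2, 1, 3)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d))
        return nn.softmax(scores, axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        tokens = x.reshape(B, C, H * W).transpose(0, 2, 1)  # (B, N, C)
        attn = self.attention_weights(tokens)
        h, d = self.num_heads, self.head_dim
        v = self.wv(tokens).reshape(B, H * W, h, d).transpose(0, 2, 1, 3)
        ctx = attn @ v  # (B, h, N, d)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, H * W, C)
        out = self.wout(ctx)
        return out.transpose(0, 2, 1).reshape(B, C, H, W)


class MpaConv(nn.Module):
    """Mask-modulated 3x3 convolution emphasizing the kernel center.

    The effective kernel is K * M with, per output channel n,

        M_n = M_base - theta * M_learn * C_mask * s_n,

    where M_base is all ones, M_learn is a learnable 3x3 mask initialized
    from U(-1, 1), C_mask has center 1 and off-center 0.5, theta is a
    learnable scalar, and s_n is the sum of filter n's input weights.  With
    theta = 0 the layer is exactly a plain convolution; theta is initialized
    small but nonzero (0.1) because at exactly 0 the learnable mask receives
    no gradient.  M is recomputed from the current parameters on every
    forward pass.
    """

    KERNEL = 3

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        k = self.KERNEL
        fan_in = in_ch * k * k
        self.weight = nn.Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, k, k)).astype(
                np.float32
            )
        )
        self.bias = nn.Parameter(np.zeros(out_ch, dtype=np.float32))
        self.mask_learn = nn.Parameter(rng.uniform(-1.0, 1.0, (k, k)).astype(np.float32))
        self.theta = nn.Parameter(np.asarray(0.1, dtype=np.float32))
        cmask = np.full((k, k), 0.5, dtype=np.float32)
        cmask[k // 2, k // 2] = 1.0
        self.center_mask = cmask  # fixed buffer

    def effective_mask(self) -> Tensor:
        """(out_ch, 1, k, k) mask M for the current parameters."""
        s = self.weight.sum(axis=(1, 2, 3))  # per-output-channel weight sum
        modulation = self.mask_learn * Tensor(self.center_mask)  # (k, k)
        k = self.KERNEL
        m = 1.0 - self.theta * modulation.reshape(1, 1, k, k) * s.reshape(-1, 1, 1, 1)
        return m

    def forward(self, x: Tensor) -> Tensor:
        keff = self.weight * self.effective_mask()
        return nn.conv2d(x, keff, self.bias, padding=self.KERNEL // 2)


def _l2_normalize_channels(x: Tensor, eps: float = 1e-8) -> Tensor:
    norm = ((x**2).sum(axis=1, keepdims=True) + eps) ** 0.5
    return x / norm


class RegionInteraction(nn.Module):
    """Cross-quadrant feature interaction.

    Channel-concatenate the four regions -> 3x3 conv + ReLU -> partition the
    channels back into four groups -> spatially reassemble into a full-size
    map -> 3x3 conv + sigmoid -> interaction map Fa.  Each region F is then
    updated as softmax(F + F * Fa_region) with the softmax over channels at
    each pixel.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.conv1 = nn.Conv2d(4 * channels, 4 * channels, 3, rng)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng)

    def interaction_map(self, fa: Tensor, fb: Tensor, fc: Tensor, fd: Tensor) -> Tensor:
        """(B, C, 2h, 2w) sigmoid interaction map over the reassembled extent."""
        cat = nn.concat([fa, fb, fc, fd], axis=1)
        mixed = self.conv1(cat).relu()
        C = self.channels
        parts = [mixed[:, i * C : (i + 1) * C, :, :] for i in range(4)]
        full = reassemble_quadrants(*parts)
        return self.conv2(full).sigmoid()

    def forward(
        self, fa: Tensor, fb: Tensor, fc: Tensor, fd: Tensor
    ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        fmap = self.interaction_map(fa, fb, fc, fd)
        qmaps = partition_quadrants(fmap)
        out = []
        for f, fa_q in zip((fa, fb, fc, fd), qmaps):
            out.append(nn.softmax(f + f * fa_q, axis=1))
        return tuple(out)


class PeripheralVisionBlock(nn.Module):
    """Quadrant partition -> per-region (MSA, MPA) branches -> interaction.

    Per region the MPA map is L2-normalized along channels and multiplied
    elementwise with the MSA output; the four combined regions then interact
    and are reassembled into a full-size feature map.
    """

    def __init__(self, channels: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        self.msa = MultiheadSelfAttention2d(channels, num_heads, rng)
        self.mpa = MpaConv(channels, channels, rng)
        self.interaction = RegionInteraction(channels, rng)

    def region_features(self, region: Tensor) -> Tensor:
        return _l2_normalize_channels(self.mpa(region)) * self.msa(region)

    def forward(self, x: Tensor) -> Tensor:
        quads = partition_quadrants(x)
        feats = [self.region_features(q) for q in quads]
        updated = self.interaction(*feats)
        return reassemble_quadrants(*updated)


class AssistantNet(nn.Module):
    """Single-modality assistant: stem -> peripheral-vision block -> decoder.

    The stem downsamples twice so that attention runs over a small token
    grid; the compact encoder-decoder head restores full resolution.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        base_channels: int = 8,
        num_attention_heads: int = 2,
    ):
        super().__init__()
        self.stem1 = DoubleConv(1, base_channels, rng)
        self.stem2 = DoubleConv(base_channels, base_channels, rng)
        self.pv = PeripheralVisionBlock(base_channels, num_attention_heads, rng)
        self.up1 = nn.Conv2d(base_channels, base_channels, 1, rng)
        self.up2 = nn.Conv2d(base_channels, base_channels, 1, rng)
        self.decoder = CompactEncoderDecoder(base_channels, NUM_CLASSES, base_channels, rng)

    def forward(self, image: Tensor) -> SegmentationOutput:
        """image: (B, 1, H, W) single-modality input, H and W divisible by 8."""
        if image.ndim != 4 or image.shape[1] != 1:
            raise ValueError(
                f"assistant takes a single-modality (B, 1, H, W) input, got {image.shape}"
            )
        x = self.stem1(image)
        x = nn.maxpool2x2(x)
        x = self.stem2(x)
        x = nn.maxpool2x2(x)
        x = self.pv(x)
        x = self.up1(nn.upsample2x(x)).relu()
        x = self.up2(nn.upsample2x(x)).relu()
        return SegmentationOutput(self.decoder(x))
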