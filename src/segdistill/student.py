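"""Single-modality student network.

The student accepts one MRI contrast (t1, t1ce, t2 or flair) and predicts
the same four classes as the teacher, using the compact encoder-decoder
backbone.  All of its segmentation skill beyond plain supervision comes from
the distillation objective.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .data import MODALITIES, MultimodalSample
from .nn import Tensor
from .teacher import NUM_CLASSES, SegmentationOutput
from .unet import CompactEncoderDecoder

__all__ = ["StudentNet", "modality_batch"]


class StudentNet(nn.Module):
    def __init__(self, rng: np.random.Generator, base_channels: int = 8):
        super().__init__()
        self.backbone = CompactEncoderDecoder(1, NUM_CLASSES, base_channels, rng)

    def forward(self, image: Tensor) -> SegmentationOutput:
        if image.ndim != 4 or image.shape[1] != 1:
            raise ValueError(
                f"student takes a single-modality (B, 1, H, W) input, got {image.shape}"
            )
        return SegmentationOutput(self.backbone(image))


def modality_batch(samples: list[MultimodalSample], modality: str) -> Tensor:
    """(B, 1, H, W) tensor of one modality across samples."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; choose from {MODALITIES}")
    return Tensor(np.stack([s.modality(modality)[None] for s in samples]))
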