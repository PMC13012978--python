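"""Deep feature capture module (DFCM).

Redistributes the bottleneck semantics to every stage of the refinement
decoder.  The bottleneck feature map is routed into four parallel
branches; branch ``i`` (i = 1..4) upsamples bilinearly by 2 ``i`` times,
passes through a channel-attention then spatial-attention gate, adds the
upsampled tensor back as a residual, and compresses with a 1x1
convolution to the channel width of encoder level ``5 - i`` so the
refinement decoder can concatenate it without further adaptation.
Each branch owns independent attention weights.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .blocks import ChannelAttention, SpatialAttention
from .nn import Conv2d, Module, ModuleList, bilinear_resize

__all__ = ["DFCM"]


class DFCM(Module):
    """Bottleneck (B, C5, S, S) -> four guidance maps.

    Branch ``i`` output: spatial side ``S * 2**i``, channels
    ``out_channels[i - 1]`` (the encoder width at the matching
    resolution).
    """

    def __init__(self, bottleneck_channels: int, out_channels: tuple[int, int, int, int],
                 rng: np.random.Generator):
        super().__init__()
        self.bottleneck_channels = bottleneck_channels
        self.out_channels = tuple(out_channels)
        self.cams = ModuleList(ChannelAttention(bottleneck_channels, rng) for _ in range(4))
        self.sams = ModuleList(SpatialAttention(rng) for _ in range(4))
        self.compress = ModuleList(
            Conv2d(bottleneck_channels, c, 1, rng) for c in self.out_channels)

    def forward(self, bottleneck: Tensor) -> list[Tensor]:
        B, C, H, W = bottleneck.shape
        if H != W:
            raise ValueError(f"DFCM expects a square bottleneck, got {H}x{W}")
        if C != self.bottleneck_channels:
            raise ValueError(f"DFCM built for {self.bottleneck_channels} channels, got {C}")
        outputs: list[Tensor] = []
        up = bottleneck
        for i in range(4):
            up = bilinear_resize(up, up.shape[2] * 2, up.shape[3] * 2)
            attended = self.sams[i](self.cams[i](up))
            fused = attended + up
            outputs.append(self.compress[i](fused))
        return outputs
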