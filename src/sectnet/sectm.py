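"""SE-convolution Transformer module (SECTM) and the encoder stage
that wraps it.

The block feeds a square (B, C, S, S) feature map into three parallel
branches: a stack of 3x3 conv + BN + ReLU layers for local detail, an
SE-ASPP block for multi-scale context, and a bilinear attention gate.
The first two are summed into a value tensor ``V``; a residual adds the
input, ``V' = V + x``; the attention map ``A`` gates the residual value,
``F = A * V' + V'``; and two parallel 3x3 refinement convolutions are
summed into the output.  The block is channel- and size-preserving.

An encoder stage is 2x2 max pooling, a channel-doubling pointwise
convolution, then a SECTM at the halved resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .blocks import SEASPP, SEBlock, BilinearAttention
from .nn import (BatchNorm2d, Conv2d, Module, ModuleList, Sequential, ReLU,
                 max_pool2x2)

__all__ = ["SectmConfig", "SECTM", "SectmEncoderStage"]


@dataclass(frozen=True)
class SectmConfig:
    """Static geometry of one SECTM instance.

    The bilinear attention branch contains fully connected layers of
    shape (S*S, S), so the block is bound to its spatial side.
    """

    channels: int
    spatial_side: int
    conv_stack_depth: int = 2
    se_aspp_mode: str = "full"   # full | se_only | aspp_only | none
    use_bam: bool = True

    def __post_init__(self):
        if self.channels < 8:
            raise ValueError(f"SectmConfig.channels must be >= 8, got {self.channels}")
        if self.spatial_side < 2:
            raise ValueError(f"SectmConfig.spatial_side must be >= 2, got {self.spatial_side}")
        if self.conv_stack_depth < 1:
            raise ValueError("conv_stack_depth must be positive")
        if self.se_aspp_mode not in ("full", "se_only", "aspp_only", "none"):
            raise ValueError(f"unknown se_aspp_mode {self.se_aspp_mode!r}")


class _AsppOnly(Module):
    """The four convolutional branches of SE-ASPP without the SE branch."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        if channels < 4:
            raise ValueError("ASPP needs at least 4 channels")
        branch_c = channels // 4
        self.branch1 = Conv2d(channels, branch_c, 1, rng)
        self.dilated = ModuleList(
            Sequential(
                Conv2d(channels, channels, 3, rng, padding=r, dilation=r, groups=channels),
                Conv2d(channels, branch_c, 1, rng),
            )
            for r in SEASPP.RATES
        )
        self.project = Conv2d(4 * branch_c, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import concat
        branches = [self.branch1(x)] + [d(x) for d in self.dilated]
        return self.project(concat(branches, axis=1))


def _conv_bn_relu(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    return Sequential(Conv2d(cin, cout, 3, rng, padding=1), BatchNorm2d(cout), ReLU())


class SECTM(Module):
    def __init__(self, cfg: SectmConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.conv_stack = Sequential(
            *[_conv_bn_relu(c, c, rng) for _ in range(cfg.conv_stack_depth)])
        if cfg.se_aspp_mode == "full":
            self.context = SEASPP(c, rng)
        elif cfg.se_aspp_mode == "se_only":
            self.context = SEBlock(c, rng)
        elif cfg.se_aspp_mode == "aspp_only":
            self.context = _AsppOnly(c, rng)
        else:
            self.context = None
        self.attention = BilinearAttention(c, cfg.spatial_side, rng) if cfg.use_bam else None
        self.refine_a = _conv_bn_relu(c, c, rng)
        self.refine_b = _conv_bn_relu(c, c, rng)

    def _check(self, x: Tensor) -> None:
        B, C, H, W = x.shape
        if C != self.cfg.channels or H != self.cfg.spatial_side or W != self.cfg.spatial_side:
            raise ValueError(
                f"SECTM configured for ({self.cfg.channels}, {self.cfg.spatial_side}, "
                f"{self.cfg.spatial_side}) got input of shape {x.shape}")

    def forward_with_intermediates(self, x: Tensor) -> dict[str, Tensor]:
        """Run the block and return every named intermediate."""
        self._check(x)
        value = self.conv_stack(x)
        if self.context is not None:
            value = value + self.context(x)
        value_res = value + x                       # V' = V + x
        if self.attention is not None:
            attn = self.attention(x)                # (B, 1, S, S), broadcast over C
            fused = attn * value_res + value_res    # F = A * V' + V'
        else:
            attn = None
            fused = value_res
        out = self.refine_a(fused) + self.refine_b(fused)
        return {"value": value, "value_res": value_res, "attention": attn,
                "fused": fused, "out": out}

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_with_intermediates(x)["out"]


class SectmEncoderStage(Module):
    """Downsampling encoder stage: 2x2 max pool, pointwise channel
    doubling, then a SECTM at the halved resolution.

    Input (B, C, S, S) -> output (B, 2C, S/2, S/2); S must be even.
    """

    def __init__(self, in_channels: int, in_side: int, rng: np.random.Generator, *,
                 conv_stack_depth: int = 2, se_aspp_mode: str = "full",
                 use_bam: bool = True):
        super().__init__()
        if in_side % 2:
            raise ValueError(f"encoder stage requires an even input side, got {in_side}")
        self.expand = Conv2d(in_channels, 2 * in_channels, 1, rng)
        self.sectm = SECTM(
            SectmConfig(channels=2 * in_channels, spatial_side=in_side // 2,
                        conv_stack_depth=conv_stack_depth,
                        se_aspp_mode=se_aspp_mode, use_bam=use_bam), rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.sectm(self.expand(max_pool2x2(x)))
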