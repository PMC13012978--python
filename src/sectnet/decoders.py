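"""The two decoding branches and the mask-interaction primitives.

Decoder1 is a classical U-Net decoder: transposed-convolution
upsampling, concatenation with the encoder skip, DoubleConv refinement,
and a 1x1 conv + sigmoid head that emits the coarse probability mask.

Decoder2 refines under guidance.  At each stage the upsampled feature
is split into two copies; one is multiplied element-wise with the
coarse mask resized to the stage resolution, and the other is added
back, giving the residual mask interaction

    add_n = up_feat * mask + up_feat.

The result is concatenated with the DFCM guidance map and the encoder
skip at that scale and refined by a DoubleConv.  Features use learned
transposed-convolution upsampling; probability masks are resized with
parameter-free bilinear interpolation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .blocks import DoubleConv
from .nn import Conv2d, ConvTranspose2x2, Module, bilinear_resize

__all__ = ["Decoder1Block", "Decoder2Block", "SegmentationHead",
           "resize_mask", "mask_fuse"]


def resize_mask(mask: Tensor, side: int) -> Tensor:
    """Bilinear resize of a (B, 1, H, W) probability mask to side x side.

    Bilinear interpolation is a convex combination, so values stay in
    [0, 1].  Downsizing then upsizing is lossy; no round trip is implied.
    """
    if mask.ndim != 4 or mask.shape[1] != 1:
        raise ValueError(f"resize_mask expects (B, 1, H, W), got {mask.shape}")
    if side < 1:
        raise ValueError("side must be positive")
    return bilinear_resize(mask, side, side)


def mask_fuse(up_feat: Tensor, mask: Tensor) -> Tensor:
    """Residual mask interaction: ``up_feat * mask + up_feat``.

    The mask (B, 1, H, W) broadcasts over channels.  A zero mask leaves
    the features unchanged; a unit mask doubles them.
    """
    if up_feat.shape[2:] != mask.shape[2:]:
        raise ValueError(f"mask_fuse: spatial mismatch between features {up_feat.shape} "
                         f"and mask {mask.shape}")
    return up_feat * mask + up_feat


class SegmentationHead(Module):
    """1x1 convolution + sigmoid producing a (B, 1, H, W) probability mask."""

    def __init__(self, cin: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(cin, 1, 1, rng)

    def forward(self, feat: Tensor) -> Tensor:
        return self.conv(feat).sigmoid()


class Decoder1Block(Module):
    """Upsample (halving channels), concatenate the encoder skip, refine.

    prev (B, C, S, S) + skip (B, C/2, 2S, 2S) -> (B, C/2, 2S, 2S).
    """

    def __init__(self, in_channels: int, rng: np.random.Generator):
        super().__init__()
        out = in_channels // 2
        self.up = ConvTranspose2x2(in_channels, out, rng)
        self.refine = DoubleConv(in_channels, out, rng)

    def forward(self, prev: Tensor, skip: Tensor) -> Tensor:
        up = self.up(prev)
        if up.shape[2:] != skip.shape[2:]:
            raise ValueError(f"Decoder1Block: skip resolution {skip.shape[2:]} does not "
                             f"match upsampled feature {up.shape[2:]}")
        return self.refine(concat([up, skip], axis=1))


class Decoder2Block(Module):
    """Mask-guided refinement stage.

    Upsamples the previous Decoder2 feature, applies the residual mask
    interaction with the coarse mask resized to this scale, then
    concatenates the DFCM guidance map and the encoder skip before a
    DoubleConv.  ``guidance`` selects the interaction:

    * ``"mask"`` — ``add_n = up * mask + up`` (the dual-decoder mask
      mechanism);
    * ``"decoder1_features"`` — ``add_n = up + d1_feat`` (direct feature
      transfer from the matching Decoder1 stage);
    * ``"none"`` — ``add_n = up``.
    """

    def __init__(self, in_channels: int, rng: np.random.Generator, *,
                 use_dfcm: bool = True, guidance: str = "mask"):
        super().__init__()
        if guidance not in ("mask", "decoder1_features", "none"):
            raise ValueError(f"unknown guidance {guidance!r}")
        out = in_channels // 2
        self.guidance = guidance
        self.use_dfcm = use_dfcm
        self.up = ConvTranspose2x2(in_channels, out, rng)
        cat_channels = out * (3 if use_dfcm else 2)
        self.refine = DoubleConv(cat_channels, out, rng)

    def forward(self, prev: Tensor, skip: Tensor, *, mask: Tensor | None = None,
                dfcm_feat: Tensor | None = None, d1_feat: Tensor | None = None) -> Tensor:
        up = self.up(prev)
        side = up.shape[2]
        if skip.shape[2:] != up.shape[2:]:
            raise ValueError(f"Decoder2Block: encoder skip {skip.shape[2:]} does not match "
                             f"upsampled feature {up.shape[2:]}")
        if self.guidance == "mask":
            if mask is None:
                raise ValueError("Decoder2Block(guidance='mask') requires the coarse mask")
            add_n = mask_fuse(up, resize_mask(mask, side))
        elif self.guidance == "decoder1_features":
            if d1_feat is None:
                raise ValueError("Decoder2Block(guidance='decoder1_features') requires d1_feat")
            if d1_feat.shape != up.shape:
                raise ValueError(f"Decoder2Block: Decoder1 feature {d1_feat.shape} does not "
                                 f"match upsampled feature {up.shape}")
            add_n = up + d1_feat
        else:
            add_n = up
        parts = [add_n]
        if self.use_dfcm:
            if dfcm_feat is None:
                raise ValueError("Decoder2Block built with use_dfcm=True requires dfcm_feat")
            if dfcm_feat.shape[2:] != up.shape[2:]:
                raise ValueError(f"Decoder2Block: DFCM feature {dfcm_feat.shape[2:]} does not "
                                 f"match upsampled feature {up.shape[2:]}")
            parts.append(dfcm_feat)
        parts.append(skip)
        return self.refine(concat(parts, axis=1))
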