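"""Reusable learned blocks of the segmentation network.

* :class:`DoubleConv` — two 3x3 conv + BN + ReLU layers (the U-Net staple).
* :class:`SEBlock` — squeeze-and-excitation channel recalibration.
* :class:`SEASPP` — atrous spatial pyramid pooling (dilated depthwise
  branches at rates 6/12/18) fused with an SE branch.
* :class:`BilinearAttention` — a second-order spatial gate built from an
  HxH outer-product correlation matrix.
* :class:`ChannelAttention` / :class:`SpatialAttention` — CBAM-style
  pooled-descriptor gates.

All blocks preserve spatial resolution, and every sigmoid gate is a
multiplicative factor: a zero input yields a zero output for the gated
blocks.  Gate-producing layers are bias-initialized to zero, so an
untrained gate starts at the neutral value 0.5.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import (BatchNorm2d, Conv2d, Linear, Module, ModuleList, Sequential,
                 ReLU, global_avg_pool, global_max_pool)

__all__ = ["DoubleConv", "SEBlock", "SEASPP", "BilinearAttention",
           "ChannelAttention", "SpatialAttention"]


class DoubleConv(Module):
    """Two consecutive 3x3 convolutions, each with batch norm and ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.block = Sequential(
            Conv2d(cin, cout, 3, rng, padding=1), BatchNorm2d(cout), ReLU(),
            Conv2d(cout, cout, 3, rng, padding=1), BatchNorm2d(cout), ReLU(),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class SEBlock(Module):
    """Squeeze-and-excitation: global pooling -> FC bottleneck -> sigmoid
    channel weights that rescale the input."""

    def __init__(self, channels: int, rng: np.random.Generator, *, reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.channels = channels
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def channel_weights(self, x: Tensor) -> Tensor:
        """(B, C, H, W) -> sigmoid weights (B, C, 1, 1), strictly in (0, 1)."""
        B, C = x.shape[0], x.shape[1]
        squeezed = global_avg_pool(x).reshape(B, C)
        # leaky rectifier: the bottleneck can be 1 unit wide, and a dead
        # ReLU there would cut the whole gate out of the gradient graph
        w = self.fc2(self.fc1(squeezed).leaky_relu()).sigmoid()
        return w.reshape(B, C, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        return x * self.channel_weights(x)


class SEASPP(Module):
    """Multi-scale context with channel recalibration.

    Five parallel branches: a 1x1 convolution, three 3x3 depthwise
    convolutions with dilation rates 6/12/18 (each followed by a
    pointwise mix), and an SE branch.  The four convolutional branches
    emit C/4 channels each, the SE branch emits C; the concatenated 2C
    channels are restored to C by a final pointwise convolution, so the
    block is C-in / C-out and size-preserving (padding = dilation).
    """

    RATES = (6, 12, 18)

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        if channels < 4:
            raise ValueError(
                f"SEASPP needs at least 4 channels (got {channels}): each of the "
                "four convolutional branches emits channels // 4 feature maps")
        branch_c = channels // 4
        self.branch1 = Conv2d(channels, branch_c, 1, rng)
        self.dilated = ModuleList(
            Sequential(
                Conv2d(channels, channels, 3, rng, padding=r, dilation=r, groups=channels),
                Conv2d(channels, branch_c, 1, rng),
            )
            for r in self.RATES
        )
        self.se = SEBlock(channels, rng)
        self.project = Conv2d(4 * branch_c + channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        branches = [self.branch1(x)]
        branches += [d(x) for d in self.dilated]
        branches.append(self.se(x))
        return self.project(concat(branches, axis=1))


class BilinearAttention(Module):
    """Second-order spatial attention gate for a square SxS feature map.

    Query and key branches each apply a 1x1 convolution to a single
    channel, flatten to S*S and reduce to S with a fully connected
    layer; the (S, 1) x (1, S) outer product gives an SxS correlation
    matrix that a final 1x1 convolution and sigmoid turn into a gate in
    [0, 1].  The map is broadcast across channels when applied (valid
    because the feature map is square).  The fully connected weights tie
    the block to its configured ``spatial_side``.
    """

    def __init__(self, channels: int, spatial_side: int, rng: np.random.Generator):
        super().__init__()
        s = spatial_side
        self.spatial_side = s
        self.query_conv = Conv2d(channels, 1, 1, rng)
        self.key_conv = Conv2d(channels, 1, 1, rng)
        self.query_fc = Linear(s * s, s, rng)
        self.key_fc = Linear(s * s, s, rng)
        self.out_conv = Conv2d(1, 1, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, _, H, W = x.shape
        if H != W:
            raise ValueError(
                f"BilinearAttention supports only square feature maps; got {H}x{W}. "
                "The outer-product correlation matrix is HxH and is broadcast as a "
                "spatial map, which requires H == W.")
        if H != self.spatial_side:
            raise ValueError(f"BilinearAttention was built for side {self.spatial_side}, "
                             f"got input side {H}")
        q = self.query_fc(self.query_conv(x).reshape(B, H * W)).reshape(B, H, 1)
        k = self.key_fc(self.key_conv(x).reshape(B, H * W)).reshape(B, 1, H)
        corr = q.matmul(k).reshape(B, 1, H, H)
        return self.out_conv(corr).sigmoid()


class ChannelAttention(Module):
    """CBAM-style channel gate: spatial max- and average-pooled
    descriptors pass through a shared two-layer bottleneck (C -> C/16 ->
    C); their sum is squashed to sigmoid weights that rescale channels."""

    def __init__(self, channels: int, rng: np.random.Generator, *, reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = Conv2d(channels, hidden, 1, rng, bias=False)
        self.fc2 = Conv2d(hidden, channels, 1, rng, bias=False)

    def gate(self, x: Tensor) -> Tensor:
        # leaky rectifier for the same reason as in SEBlock
        mx = self.fc2(self.fc1(global_max_pool(x)).leaky_relu())
        av = self.fc2(self.fc1(global_avg_pool(x)).leaky_relu())
        return (mx + av).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)


class SpatialAttention(Module):
    """CBAM-style spatial gate: channel-max and channel-mean maps are
    added element-wise, passed through a 7x7 convolution and a sigmoid,
    and the resulting map rescales every channel."""

    def __init__(self, rng: np.random.Generator, *, kernel: int = 7):
        super().__init__()
        self.conv = Conv2d(1, 1, kernel, rng, padding=kernel // 2)

    def gate(self, x: Tensor) -> Tensor:
        pooled = x.amax(axis=1, keepdims=True) + x.mean(axis=1, keepdims=True)
        return self.conv(pooled).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gate(x)
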