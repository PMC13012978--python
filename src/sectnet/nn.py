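"""Neural-network layers on top of the :mod:`sectnet.autodiff` engine.

Provides the layer vocabulary of an encoder-decoder segmentation
network: 2-D convolution (stride 1, arbitrary padding/dilation/groups),
2x2 stride-2 transposed convolution, 2x2 max pooling, bilinear
interpolation, batch normalization and fully connected layers, plus a
torch-like :class:`Module` container with parameter registration,
train/eval modes and state dicts.

Convolutions are evaluated by unfolding the input into kernel-position
slices and contracting with BLAS matmuls; backward passes reuse the
unfolded view, so memory stays proportional to ``k*k`` copies of the
activation.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Sequential",
    "Conv2d",
    "ConvTranspose2x2",
    "BatchNorm2d",
    "Linear",
    "ReLU",
    "Sigmoid",
    "MaxPool2x2",
    "conv2d",
    "conv_transpose2x2",
    "max_pool2x2",
    "bilinear_resize",
    "batch_norm2d",
    "global_avg_pool",
    "global_max_pool",
]


# --------------------------------------------------------------------------
# functional ops
# --------------------------------------------------------------------------

def _check_4d(x: Tensor, who: str) -> None:
    if x.ndim != 4:
        raise ValueError(f"{who} expects a 4-D (B, C, H, W) input, got shape {x.shape}")


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, padding: int = 0,
           dilation: int = 1, groups: int = 1) -> Tensor:
    """Stride-1 2-D cross-correlation with padding, dilation and groups."""
    _check_4d(x, "conv2d")
    B, Cin, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    G = groups
    if Cin != Cg * G:
        raise ValueError(f"conv2d: input channels {Cin} incompatible with weight "
                         f"{w.shape} and groups {G}")
    p, d = padding, dilation
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Ho = H + 2 * p - d * (kh - 1)
    Wo = W + 2 * p - d * (kw - 1)
    if Ho < 1 or Wo < 1:
        raise ValueError("conv2d: kernel does not fit the (padded) input")
    col = np.empty((B, Cin, kh, kw, Ho, Wo), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = xp[:, :, i * d:i * d + Ho, j * d:j * d + Wo]
    K = Cg * kh * kw
    L = Ho * Wo
    col2 = col.reshape(B, G, K, L)
    w2 = w.data.reshape(G, Cout // G, K)
    out = np.matmul(w2[None], col2)          # (B, G, Cout/G, L)
    out = out.reshape(B, Cout, Ho, Wo)
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1)

    def bw(g):
        go = g.reshape(B, G, Cout // G, L)
        if w.requires_grad:
            gw = np.matmul(go, col2.transpose(0, 1, 3, 2)).sum(axis=0)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcol = np.matmul(w2.transpose(0, 2, 1)[None], go)  # (B, G, K, L)
            gcol = gcol.reshape(B, Cin, kh, kw, Ho, Wo)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i * d:i * d + Ho, j * d:j * d + Wo] += gcol[:, :, i, j]
            x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._make(out, parents, bw)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact x2 upsampling).

    Weight shape is ``(Cin, Cout, 2, 2)``; output spatial size doubles.
    """
    _check_4d(x, "conv_transpose2x2")
    B, Cin, H, W = x.shape
    if w.shape[0] != Cin or w.shape[2:] != (2, 2):
        raise ValueError(f"conv_transpose2x2: weight {w.shape} incompatible with input {x.shape}")
    Cout = w.shape[1]
    out = np.empty((B, Cout, 2 * H, 2 * W), dtype=np.float32)
    x2 = x.data.reshape(B, Cin, H * W)
    for i in range(2):
        for j in range(2):
            wij = w.data[:, :, i, j]                       # (Cin, Cout)
            out[:, :, i::2, j::2] = np.matmul(wij.T[None], x2).reshape(B, Cout, H, W)
    if b is not None:
        out += b.data.reshape(1, Cout, 1, 1)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        for i in range(2):
            for j in range(2):
                gij = g[:, :, i::2, j::2].reshape(B, Cout, H * W)
                if w.requires_grad:
                    gw = np.matmul(x2, gij.transpose(0, 2, 1)).sum(axis=0)  # (Cin, Cout)
                    w._accum(_pad_slot(gw, w.shape, i, j))
                if gx is not None:
                    gx += np.matmul(w.data[:, :, i, j][None], gij).reshape(B, Cin, H, W)
        if gx is not None:
            x._accum(gx)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._make(out, parents, bw)


def _pad_slot(gw: np.ndarray, shape: tuple, i: int, j: int) -> np.ndarray:
    full = np.zeros(shape, dtype=np.float32)
    full[:, :, i, j] = gw
    return full


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; spatial dims must be even."""
    _check_4d(x, "max_pool2x2")
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"max_pool2x2 requires even spatial dims, got {H}x{W}")
    xr = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
    out = xr.max(axis=(3, 5))
    mask = xr == out[:, :, :, None, :, None]
    count = mask.sum(axis=(3, 5), keepdims=True)

    def bw(g):
        gx = mask * (g[:, :, :, None, :, None] / count)
        x._accum(gx.reshape(B, C, H, W))

    return Tensor._make(out, (x,), bw)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix, half-pixel-center convention."""
    M = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    scale = n_in / n_out
    for o in range(n_out):
        s = (o + 0.5) * scale - 0.5
        s = min(max(s, 0.0), n_in - 1.0)
        i0 = int(np.floor(s))
        i1 = min(i0 + 1, n_in - 1)
        t = s - i0
        M[o, i0] += 1.0 - t
        M[o, i1] += t
    return M


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Differentiable separable bilinear resize of a (B, C, H, W) tensor."""
    _check_4d(x, "bilinear_resize")
    B, C, H, W = x.shape
    Mr = _interp_matrix(out_h, H)
    Mc = _interp_matrix(out_w, W)
    out = np.matmul(np.matmul(Mr, x.data), Mc.T)

    def bw(g):
        x._accum(np.matmul(np.matmul(Mr.T, g), Mc))

    return Tensor._make(out, (x,), bw)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, *, training: bool,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (B, H, W).

    In training mode the batch statistics (biased variance) normalize the
    activations and the running buffers are updated in place with the
    unbiased variance.  In eval mode the running buffers are used.
    """
    _check_4d(x, "batch_norm2d")
    B, C, H, W = x.shape
    axes = (0, 2, 3)
    if training:
        n = B * H * W
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * (var * (n / max(n - 1, 1)))
    else:
        mu = running_mean
        var = running_var
    std = np.sqrt(var + eps).astype(np.float32)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) / std.reshape(1, C, 1, 1)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(1, C, 1, 1)
            if training:
                m1 = gxhat.mean(axis=axes, keepdims=True)
                m2 = (gxhat * xhat).mean(axis=axes, keepdims=True)
                gx = (gxhat - m1 - xhat * m2) / std.reshape(1, C, 1, 1)
            else:
                gx = gxhat / std.reshape(1, C, 1, 1)
            x._accum(gx)

    return Tensor._make(out, (x, gamma, beta), bw)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C, 1, 1) spatial mean."""
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    """(B, C, H, W) -> (B, C, 1, 1) spatial max."""
    return x.amax(axis=(2, 3), keepdims=True)


# --------------------------------------------------------------------------
# module system
# --------------------------------------------------------------------------

class Module:
    """Base class with automatic parameter / submodule registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own_p = dict(self.named_parameters())
        own_b = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = own_b[key[len("buffer:"):]]
                if buf.shape != value.shape:
                    raise ValueError(f"buffer shape mismatch for {key}")
                buf[...] = value
            else:
                p = own_p[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"parameter shape mismatch for {key}: "
                                     f"{p.data.shape} vs {value.shape}")
                p.data = value.astype(np.float32).copy()

    # -- modes -------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module) -> None:
        self._modules[str(len(self._list))] = m
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self._list:
            x = m(x)
        return x


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

def _he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _xavier(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2d(Module):
    """Stride-1 convolution; weights He-initialized, biases zero."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator, *,
                 padding: int = 0, dilation: int = 1, groups: int = 1, bias: bool = True):
        super().__init__()
        if cin % groups or cout % groups:
            raise ValueError("channels must be divisible by groups")
        fan_in = (cin // groups) * kernel * kernel
        self.weight = Parameter(_he_normal(rng, (cout, cin // groups, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None
        self.padding = padding
        self.dilation = dilation
        self.groups = groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, padding=self.padding,
                      dilation=self.dilation, groups=self.groups)


class ConvTranspose2x2(Module):
    """Kernel-2 stride-2 transposed convolution (exact x2 upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, *, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_he_normal(rng, (cin, cout, 2, 2), cin * 4))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, *, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.eps = eps
        self.momentum = momentum

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.gamma, self.beta, training=self.training,
                            running_mean=self.running_mean, running_var=self.running_var,
                            momentum=self.momentum, eps=self.eps)


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator, *, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_xavier(rng, (fout, fin), fin, fout))
        self.bias = Parameter(np.zeros(fout, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x.matmul(Tensor._make(self.weight.data.T, (self.weight,),
                                    lambda g: self.weight._accum(g.T)))
        if self.bias is not None:
            out = out + self.bias
        return out


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return max_pool2x2(x)
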