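"""First-order optimizers for the numpy autodiff engine.

The registry mirrors the optimizer families commonly benchmarked for
this architecture: Adam and its variants (AdamW, Adamax, NAdam),
RMSprop, Rprop and SGD with momentum.  Update rules follow the standard
published formulations with their conventional default hyperparameters.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter

__all__ = ["OPTIMIZERS", "make_optimizer", "Optimizer", "SGD", "Adam", "AdamW",
           "Adamax", "NAdam", "RMSprop", "Rprop"]


class Optimizer:
    def __init__(self, params: list[Parameter], lr: float):
        self.params = list(params)
        self.lr = float(lr)
        self.t = 0
        self.state: list[dict] = [{} for _ in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, st in zip(self.params, self.state):
            if p.grad is None:
                continue
            self._update(p, p.grad, st)

    def _update(self, p: Parameter, g: np.ndarray, st: dict) -> None:
        raise NotImplementedError


class SGD(Optimizer):
    def __init__(self, params, lr, momentum: float = 0.9):
        super().__init__(params, lr)
        self.momentum = momentum

    def _update(self, p, g, st):
        v = st.setdefault("v", np.zeros_like(p.data))
        v *= self.momentum
        v += g
        p.data -= self.lr * v


class Adam(Optimizer):
    def __init__(self, params, lr, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decoupled: bool = False):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled

    def _update(self, p, g, st):
        if self.weight_decay and not self.decoupled:
            g = g + self.weight_decay * p.data
        m = st.setdefault("m", np.zeros_like(p.data))
        v = st.setdefault("v", np.zeros_like(p.data))
        m *= self.b1
        m += (1 - self.b1) * g
        v *= self.b2
        v += (1 - self.b2) * g * g
        mhat = m / (1 - self.b1 ** self.t)
        vhat = v / (1 - self.b2 ** self.t)
        if self.weight_decay and self.decoupled:
            p.data -= self.lr * self.weight_decay * p.data
        p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class AdamW(Adam):
    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-2):
        super().__init__(params, lr, betas, eps, weight_decay, decoupled=True)


class Adamax(Optimizer):
    def __init__(self, params, lr, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps

    def _update(self, p, g, st):
        m = st.setdefault("m", np.zeros_like(p.data))
        u = st.setdefault("u", np.zeros_like(p.data))
        m *= self.b1
        m += (1 - self.b1) * g
        np.maximum(self.b2 * u, np.abs(g), out=u)
        p.data -= (self.lr / (1 - self.b1 ** self.t)) * m / (u + self.eps)


class NAdam(Optimizer):
    """Adam with Nesterov momentum (momentum-decay schedule omitted)."""

    def __init__(self, params, lr, betas=(0.9, 0.999), eps: float = 1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps

    def _update(self, p, g, st):
        m = st.setdefault("m", np.zeros_like(p.data))
        v = st.setdefault("v", np.zeros_like(p.data))
        m *= self.b1
        m += (1 - self.b1) * g
        v *= self.b2
        v += (1 - self.b2) * g * g
        mhat = (self.b1 * m + (1 - self.b1) * g) / (1 - self.b1 ** (self.t + 1))
        vhat = v / (1 - self.b2 ** self.t)
        p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, params, lr, alpha: float = 0.99, eps: float = 1e-8):
        super().__init__(params, lr)
        self.alpha = alpha
        self.eps = eps

    def _update(self, p, g, st):
        v = st.setdefault("v", np.zeros_like(p.data))
        v *= self.alpha
        v += (1 - self.alpha) * g * g
        p.data -= self.lr * g / (np.sqrt(v) + self.eps)


class Rprop(Optimizer):
    def __init__(self, params, lr, etas=(0.5, 1.2), step_sizes=(1e-6, 50.0)):
        super().__init__(params, lr)
        self.eta_minus, self.eta_plus = etas
        self.step_min, self.step_max = step_sizes

    def _update(self, p, g, st):
        prev = st.setdefault("prev", np.zeros_like(p.data))
        step = st.setdefault("step", np.full_like(p.data, self.lr))
        sign = np.sign(prev * g)
        step[sign > 0] = np.minimum(step[sign > 0] * self.eta_plus, self.step_max)
        step[sign < 0] = np.maximum(step[sign < 0] * self.eta_minus, self.step_min)
        g = g.copy()
        g[sign < 0] = 0.0
        p.data -= step * np.sign(g)
        prev[...] = g


OPTIMIZERS: dict[str, type[Optimizer]] = {
    "sgd": SGD,
    "adam": Adam,
    "adamw": AdamW,
    "adamax": Adamax,
    "nadam": NAdam,
    "rmsprop": RMSprop,
    "rprop": Rprop,
}


def make_optimizer(name: str, params: list[Parameter], lr: float) -> Optimizer:
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; available: {sorted(OPTIMIZERS)}") from None
    return cls(params, lr)
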