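import numpy as np
import pytest

from sectnet.autodiff import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rand_tensor(rng, shape, scale=1.0, requires_grad=False):
    t = Tensor(rng.normal(0.0, scale, size=shape).astype(np.float32))
    t.requires_grad = requires_grad
    return t


def numerical_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar-valued f() w.r.t. x (in place)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


def zero_parameters(module) -> None:
    """Zero every learnable parameter of a module (closed-form fixed points)."""
    for p in module.parameters():
        p.data = np.zeros_like(p.data)
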