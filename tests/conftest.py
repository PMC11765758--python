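import numpy as np
import pytest

from capest.autodiff import Tensor


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def to_float64(module):
    """Promote a module's parameters to float64 for finite-difference work."""
    for p in module.parameters():
        p.data = p.data.astype(np.float64)
    return module


def numerical_grad(fn, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gf = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + step
        hi = fn(x)
        flat[i] = orig - step
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * step)
    return g


def analytic_grad(fn, x: np.ndarray) -> np.ndarray:
    """Backprop gradient of a scalar Tensor function of an array."""
    t = Tensor(np.asarray(x, dtype=np.float64), requires_grad=True,
               dtype=np.float64)
    out = fn(t)
    out.backward()
    return t.grad
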