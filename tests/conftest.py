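import numpy as np
import pytest

from pestfusion.autodiff import Tensor
from pestfusion.config import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    return ModelConfig.tiny()


def numeric_gradient(fn, arrs, eps: float = 1e-6):
    """Central finite differences of a scalar-valued fn over numpy inputs."""
    grads = []
    for target in range(len(arrs)):
        arr = arrs[target]
        g = np.zeros_like(arr, dtype=float)
        flat = arr.reshape(-1)
        gflat = g.reshape(-1)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            up = float(fn(*[Tensor(a) for a in arrs]).item())
            flat[i] = orig - eps
            dn = float(fn(*[Tensor(a) for a in arrs]).item())
            flat[i] = orig
            gflat[i] = (up - dn) / (2 * eps)
        grads.append(g)
    return grads


def assert_gradcheck(fn, *arrs, tol: float = 1e-5):
    """Backward pass agrees with central finite differences."""
    tensors = [Tensor(a, requires_grad=True) for a in arrs]
    out = fn(*tensors)
    out.backward()
    numeric = numeric_gradient(fn, [np.array(a, dtype=float) for a in arrs])
    for t, num in zip(tensors, numeric):
        assert t.grad is not None
        np.testing.assert_allclose(t.grad, num, atol=tol, rtol=tol)
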