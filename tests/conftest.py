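import numpy as np
import pytest

from lgmanet import nn


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central finite differences of a scalar-valued f at x (float64)."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def check_grad(op, shapes, seed=0, atol=2e-2, rtol=2e-2, scale=1.0):
    """Compare autodiff gradients of sum(op(*tensors)) against finite
    differences for every input."""
    gen = np.random.default_rng(seed)
    arrays = [gen.standard_normal(s).astype(np.float32) * scale for s in shapes]
    tensors = [nn.Tensor(a.copy(), requires_grad=True) for a in arrays]
    out = op(*tensors)
    out.sum().backward()
    for i, (arr, ten) in enumerate(zip(arrays, tensors)):
        def f(x, i=i):
            args = [nn.Tensor(a) for a in arrays]
            args[i] = nn.Tensor(x.astype(np.float32))
            return float(op(*args).sum().data)
        num = numeric_grad(f, arr.astype(np.float64))
        ana = ten.grad
        assert ana is not None, f"input {i} received no gradient"
        np.testing.assert_allclose(ana, num, atol=atol, rtol=rtol,
                                   err_msg=f"gradient mismatch on input {i}")
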