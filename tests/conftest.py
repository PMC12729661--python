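import numpy as np
import pytest

from emaseg.nn.autograd import Tensor


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_phantom():
    """A quiet 128-px phantom pair (moderate speckle, fixed seed)."""
    from emaseg.phantom import PhantomParams, generate_phantom

    params = PhantomParams(seed=0)
    return generate_phantom(params, seed=7)


def rand_tensor(rng, shape, scale=1.0, requires_grad=False, dtype=np.float64):
    return Tensor((rng.standard_normal(shape) * scale).astype(dtype),
                  requires_grad=requires_grad)


def numeric_grad(fn, tensors, which, eps=1e-6):
    """Central finite differences of scalar fn w.r.t. tensors[which]."""
    t = tensors[which]
    g = np.zeros_like(t.data)
    flat = t.data.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        f1 = fn(tensors)
        flat[i] = orig - eps
        f2 = fn(tensors)
        flat[i] = orig
        gf[i] = (f1 - f2) / (2 * eps)
    return g
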