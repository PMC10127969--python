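import numpy as np
import pytest

from mbsnet import autograd as ag


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def numeric_grad(f, arr, eps=1e-2):
    """Central-difference gradient of scalar f with respect to array arr."""
    g = np.zeros_like(arr, dtype=np.float64)
    flat = arr.reshape(-1)
    gflat = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g


def check_gradient(build, tensors, rtol=5e-2, atol=5e-3):
    """Compare autograd gradients of ``build()`` (scalar Tensor) against
    finite differences for each tensor in ``tensors``."""
    out = build()
    out.backward()
    for t in tensors:
        assert t.grad is not None, "missing gradient"
        num = numeric_grad(lambda: float(build().data), t.data)
        np.testing.assert_allclose(t.grad, num, rtol=rtol, atol=atol)


@pytest.fixture
def tiny_dataset(tmp_path):
    """A 6-image 32x32 synthetic dataset with train/val/test splits."""
    from mbsnet.data_synth import SynthConfig, generate_dataset
    root = tmp_path / "data"
    cfg = SynthConfig(image_size=32, seed=7)
    generate_dataset(cfg, n=6, out_dir=root, split=(0.5, 0.25, 0.25))
    return root


def weighted_sum(t, seed=0):
    """Deterministic scalar functional of a tensor (for gradient checks)."""
    w = np.random.default_rng(seed).normal(size=t.shape).astype(np.float32)
    return ag.tsum(ag.mul(t, ag.Tensor(w)))
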