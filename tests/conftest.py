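import numpy as np
import pytest

from genepu.io_formats import KernelMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_psd_kernel(rng):
    """Factory for random PSD kernels with explicit generating points."""

    def make(n=8, d=3, ids=None):
        x = rng.normal(size=(n, d))
        k = x @ x.T
        ids = ids or [f"g{i}" for i in range(n)]
        return KernelMatrix(ids=ids, values=k), x

    return make
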