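import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    from angioseg.network import NetworkConfig
    return NetworkConfig(embed_dim=16)


@pytest.fixture(scope="session")
def easy_phantom():
    from angioseg.phantoms import make_sample
    return make_sample(42, frame_size=128, regime="easy")


def numeric_grad(f, x, eps=1e-6):
    """Central finite-difference gradient of scalar f() w.r.t. array x,
    mutating x in place while probing."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x0 = x[i]
        x[i] = x0 + eps
        f1 = f()
        x[i] = x0 - eps
        f2 = f()
        x[i] = x0
        g[i] = (f1 - f2) / (2 * eps)
    return g
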