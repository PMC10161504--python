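import numpy as np
import pytest

from secmap._nn import autograd as ag
from secmap.pairwise_encoder import ModelConfig
from secmap.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture
def float64_autograd(monkeypatch):
    """Run the autodiff engine in float64 (finite-difference headroom)."""
    monkeypatch.setattr(ag, "DEFAULT_DTYPE", np.float64)
    yield


@pytest.fixture
def small_config():
    """A desk-scale full-variant model configuration."""
    return ModelConfig(embed_dim=32, n_layers=2, n_heads=4,
                       detector_channels=8, head_hidden=32, n_classes=8)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 synthetic proteins of length 24 with embeddings."""
    config = SynthConfig(n_proteins=12, length=24, seed=3)
    records, embeddings = generate_dataset(config)
    return config, records, embeddings


def finite_difference_grad(fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of a scalar-valued fn at x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = fn(x)
        flat[i] = orig - eps
        lo = fn(x)
        flat[i] = orig
        gf[i] = (hi - lo) / (2 * eps)
    return g
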