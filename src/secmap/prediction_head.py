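"""Per-residue classification from the pairwise feature's diagonal.

Residue i's descriptor is the channel vector at position (i, i) of the
detector output: after stacked convolutions that entry summarizes the
local bond pattern around residue i.  Two fully connected layers map it to
class logits over the DSSP8 or DSSP3 alphabet.
"""

from __future__ import annotations

import numpy as np

from ._nn import autograd as ag
from ._nn.autograd import Module, Tensor
from ._nn.layers import Linear
from .pairwise_encoder import ModelConfig
from .segment_detector import PairwiseFeature


def extract_diagonal(feature) -> np.ndarray:
    """(P, P, C) -> (P, C): row i is feature[i, i, :]."""
    values = feature.values if isinstance(feature, PairwiseFeature) else np.asarray(feature)
    if values.ndim != 3 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square (P, P, C) feature, got {values.shape}")
    p = values.shape[0]
    idx = np.arange(p)
    return values[idx, idx, :]


class PredictionHead(Module):
    """linear(C -> hidden) -> ReLU -> linear(hidden -> K)."""

    def __init__(self, in_dim: int, hidden: int, n_classes: int,
                 rng: np.random.Generator):
        self.in_dim = in_dim
        self.fc1 = Linear(in_dim, hidden, rng)
        self.fc2 = Linear(hidden, n_classes, rng)

    def forward(self, diag: Tensor) -> Tensor:
        """Returns logits (p, K)."""
        if diag.shape[-1] != self.in_dim:
            raise ValueError(
                f"head expects {self.in_dim}-dim descriptors, got {diag.shape[-1]}")
        return self.fc2(ag.relu(self.fc1(diag)))


def classify(diag: np.ndarray, head: PredictionHead | None = None,
             config: ModelConfig | None = None, seed: int = 0) -> np.ndarray:
    """Per-residue class probabilities (p, K); rows sum to 1."""
    diag = np.asarray(diag, dtype=np.float32)
    if head is None:
        if config is None:
            raise ValueError("need either a head or a config")
        head = PredictionHead(diag.shape[-1], config.head_hidden,
                              config.n_classes, np.random.default_rng(seed))
    probs = ag.softmax(head(Tensor(diag)), axis=-1)
    return probs.numpy()
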