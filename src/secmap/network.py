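"""End-to-end predictor assembling encoder, segment detector and head.

Three variants share this class:

* ``full`` — embeddings -> transformer encoder -> attention stack ->
  segment detector -> diagonal -> FC head (the proposed architecture);
* ``transformer_only`` — the encoder's hidden states feed the head
  directly, skipping the pairwise stage (ablation);
* ``external_attention`` — an externally supplied attention stack (e.g.
  from the language model itself) feeds the detector, skipping the
  encoder (ablation).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from ._nn import autograd as ag
from ._nn.autograd import Module, Tensor
from .pairwise_encoder import ModelConfig, PairwiseEncoder
from .prediction_head import PredictionHead
from .segment_detector import SegmentDetector


def external_similarity_stack(embedding: np.ndarray, n_channels: int = 1) -> np.ndarray:
    """Row-softmax scaled-similarity maps standing in for a language
    model's own attention, for the external_attention variant.

    Channel c uses temperature 2**c on E E^T / sqrt(d); returns (p, p, C).
    """
    E = np.asarray(embedding, dtype=np.float32)
    sim = (E @ E.T) / np.sqrt(E.shape[1])
    maps = []
    for c in range(n_channels):
        z = sim / float(2 ** c)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        maps.append(e / e.sum(axis=1, keepdims=True))
    return np.stack(maps, axis=-1)


class SecondaryStructureNet(Module):
    """The configurable predictor; forward maps (p, d) embeddings to logits."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator,
                 external_stack_channels: int = 1):
        self.config = config
        v = config.variant
        self.encoder = (PairwiseEncoder(config, rng)
                        if v in ("full", "transformer_only") else None)
        if v == "full":
            det_in = config.stack_channels
        elif v == "external_attention":
            det_in = external_stack_channels
        else:
            det_in = None
        self.detector = (SegmentDetector(det_in, rng, config.detector_channels)
                         if det_in is not None else None)
        head_in = (config.d_model if v == "transformer_only"
                   else 3 * config.detector_channels)
        self.head = PredictionHead(head_in, config.head_hidden,
                                   config.n_classes, rng)

    def forward(self, embedding: Tensor,
                external_stack: Optional[Tensor] = None) -> Tensor:
        v = self.config.variant
        if v == "transformer_only":
            hidden, _ = self.encoder(embedding)
            return self.head(hidden)
        if v == "full":
            _, stack = self.encoder(embedding)        # (N*H, p, p)
        else:
            if external_stack is None:
                raise ValueError(
                    "external_attention variant needs an attention stack")
            stack = external_stack
        feature = self.detector(stack)                # (3*C, p, p)
        diag = ag.take_diagonal(feature)              # (p, 3*C)
        return self.head(diag)

    def predict_proba(self, embedding: np.ndarray,
                      external_stack: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-residue class probabilities as a plain array."""
        ext = None
        if external_stack is not None:
            ext = Tensor(np.transpose(np.asarray(external_stack), (2, 0, 1)))
        logits = self.forward(Tensor(np.asarray(embedding)), ext)
        return ag.softmax(logits, axis=-1).numpy()

    # ---- bookkeeping ----------------------------------------------------

    def parameter_count(self) -> int:
        return self.n_parameters()

    def component_parameter_counts(self) -> dict[str, int]:
        counts = {}
        for comp in ("encoder", "detector", "head"):
            mod = getattr(self, comp)
            counts[comp] = mod.n_parameters() if mod is not None else 0
        enc = self.encoder
        counts["position_bias_table"] = (
            int(enc.bias_table.data.size)
            if enc is not None and enc.bias_table is not None else 0)
        counts["total"] = self.n_parameters()
        return counts

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"{name}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()
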