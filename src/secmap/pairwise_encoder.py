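"""Transformer encoder whose post-softmax attention maps are the product.

The encoder reads a (p, d) per-residue embedding matrix and, besides its
hidden states, exposes every layer's and head's post-softmax attention map
stacked into a (p, p, N*H) pairwise feature.  Position information enters
through a modified relative position encoding: a learnable bias table
indexed by a *symmetric, linearly growing* bucket of the residue-pair
distance, added to the attention logits.  Symmetry (bucket(i,j) ==
bucket(j,i)) reflects that a hydrogen bond between residues i and j is the
same bond seen from either end; linear growth keeps nearby distances —
where an i,i+3 bond (3-turn helix) must be told apart from an i,i+4 bond
(4-turn helix) — in distinct buckets.

With the default 3 layers x 8 heads the stack has 24 channels, and the
bias table (16 buckets x 8 heads, shared across layers) adds exactly 128
learnable parameters over a position-free encoder.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import yaml

from ._nn import autograd as ag
from ._nn.autograd import Module, Parameter, Tensor
from ._nn.layers import LayerNorm, Linear

PE_MODES = ("rpe", "none", "ape", "rpe+ape")
VARIANTS = ("full", "transformer_only", "external_attention")


@dataclass
class ModelConfig:
    """Architecture hyperparameters for the full predictor."""

    n_layers: int = 3
    n_heads: int = 8
    embed_dim: int = 1024
    d_model: Optional[int] = None      # defaults to embed_dim
    ff_dim: Optional[int] = None       # defaults to 4 * d_model
    n_buckets: int = 16
    pe_mode: str = "rpe"
    ape_max_len: int = 1024
    detector_channels: int = 64
    head_hidden: int = 128
    n_classes: int = 8
    variant: str = "full"

    def __post_init__(self):
        if self.d_model is None:
            self.d_model = self.embed_dim
        if self.ff_dim is None:
            self.ff_dim = 4 * self.d_model
        if min(self.n_layers, self.n_heads, self.n_buckets) < 1:
            raise ValueError("n_layers, n_heads and n_buckets must be >= 1")
        if self.n_classes not in (3, 8):
            raise ValueError("n_classes must be 3 (DSSP3) or 8 (DSSP8)")
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}"
            )
        if self.pe_mode not in PE_MODES:
            raise ValueError(f"pe_mode must be one of {PE_MODES}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @property
    def stack_channels(self) -> int:
        return self.n_layers * self.n_heads

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class AttentionStack:
    """Post-softmax attention maps: (p, p, N*H), layer-major channel order."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("attention stack must be (p, p, channels)")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


def relative_bucket(i, j, n_buckets: int):
    """Bucket of the pair (i, j): min(|i - j|, n_buckets - 1).

    Symmetric in its arguments and growing linearly with distance until the
    final bucket absorbs everything farther away.  Accepts scalars or
    arrays.
    """
    if n_buckets < 1:
        raise ValueError("n_buckets must be >= 1")
    d = np.abs(np.asarray(i, dtype=np.int64) - np.asarray(j, dtype=np.int64))
    return np.minimum(d, n_buckets - 1)


def bucket_matrix(p: int, n_buckets: int) -> np.ndarray:
    idx = np.arange(p)
    return relative_bucket(idx[:, None], idx[None, :], n_buckets)


def sinusoidal_encoding(p: int, d: int) -> np.ndarray:
    """Classic fixed sinusoidal absolute position encoding (p, d)."""
    pos = np.arange(p)[:, None].astype(np.float64)
    dim = np.arange(d)[None, :]
    angle = pos / np.power(10000.0, (2 * (dim // 2)) / d)
    enc = np.where(dim % 2 == 0, np.sin(angle), np.cos(angle))
    return enc.astype(np.float32)


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.n_heads = n_heads
        self.head_dim = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor, bias: Optional[Tensor]):
        p = x.shape[0]
        H, dh = self.n_heads, self.head_dim

        def split(t):
            return ag.permute(ag.reshape(t, (p, H, dh)), (1, 0, 2))  # (H,p,dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        logits = ag.matmul(q, ag.permute(k, (0, 2, 1))) * (1.0 / np.sqrt(dh))
        if bias is not None:
            logits = logits + bias
        attn = ag.softmax(logits, axis=-1)          # (H, p, p)
        ctx = ag.matmul(attn, v)                    # (H, p, dh)
        merged = ag.reshape(ag.permute(ctx, (1, 0, 2)), (p, H * dh))
        return self.wo(merged), attn


class EncoderLayer(Module):
    """Pre-norm transformer block with a GELU feed-forward."""

    def __init__(self, d_model: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator):
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, ff_dim, rng)
        self.ff2 = Linear(ff_dim, d_model, rng)

    def forward(self, x: Tensor, bias: Optional[Tensor]):
        a, attn = self.attn(self.ln1(x), bias)
        x = x + a
        x = x + self.ff2(ag.gelu(self.ff1(self.ln2(x))))
        return x, attn


class PairwiseEncoder(Module):
    """N-layer encoder returning hidden states and the attention stack."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        d = config.d_model
        self.project = (None if config.embed_dim == d
                        else Linear(config.embed_dim, d, rng))
        self.layers = [EncoderLayer(d, config.n_heads, config.ff_dim, rng)
                       for _ in range(config.n_layers)]
        if "rpe" in config.pe_mode:
            # one table shared by all layers: n_buckets x n_heads
            self.bias_table = Parameter(
                rng.normal(0.0, 0.02, size=(config.n_buckets, config.n_heads)))
        else:
            self.bias_table = None

    def position_bias(self, p: int) -> Optional[Tensor]:
        if self.bias_table is None:
            return None
        buckets = bucket_matrix(p, self.config.n_buckets)
        bias = ag.lookup(self.bias_table, buckets)      # (p, p, H)
        return ag.permute(bias, (2, 0, 1))              # (H, p, p)

    def forward(self, emb: Tensor):
        cfg = self.config
        p = emb.shape[0]
        if "ape" in cfg.pe_mode:
            if p > cfg.ape_max_len:
                raise ValueError(
                    f"sequence length {p} exceeds ape_max_len={cfg.ape_max_len}; "
                    "absolute position encoding cannot extrapolate"
                )
            emb = emb + Tensor(sinusoidal_encoding(p, cfg.embed_dim))
        x = self.project(emb) if self.project is not None else emb
        bias = self.position_bias(p)
        maps = []
        for layer in self.layers:
            x, attn = layer(x, bias)
            maps.append(attn)
        stack = ag.concat(maps, axis=0)  # (N*H, p, p), layer-major
        return x, stack


def build_position_bias(p: int, config: ModelConfig,
                        table: Optional[np.ndarray] = None) -> np.ndarray:
    """Materialize the relative-position bias as a (p, p, H) array.

    Entry (i, j, h) is table[bucket(i, j), h]; the table defaults to zeros
    and in the trained model is the encoder's learnable `bias_table`.
    """
    if "rpe" not in config.pe_mode:
        raise ValueError(f"pe_mode={config.pe_mode!r} has no relative position bias")
    if table is None:
        table = np.zeros((config.n_buckets, config.n_heads), dtype=np.float32)
    table = np.asarray(table)
    if table.shape != (config.n_buckets, config.n_heads):
        raise ValueError(
            f"bias table must be ({config.n_buckets}, {config.n_heads})")
    return table[bucket_matrix(p, config.n_buckets)]


def encode(embedding, config: ModelConfig,
           encoder: Optional[PairwiseEncoder] = None,
           seed: int = 0):
    """Run the encoder; returns (hidden (p, d_model), AttentionStack).

    A fresh randomly initialized encoder is built unless one is supplied.
    """
    from .embeddings import EmbeddingMatrix

    values = embedding.values if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    if not np.isfinite(values).all():
        raise ValueError("embedding contains non-finite values")
    if encoder is None:
        encoder = PairwiseEncoder(config, np.random.default_rng(seed))
    hidden, stack = encoder(Tensor(values))
    return hidden.numpy(), AttentionStack(np.transpose(stack.numpy(), (1, 2, 0)))
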