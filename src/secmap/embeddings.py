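"""Per-residue embedding matrices, stored one HDF5 dataset per protein id.

The default contract is the ProtT5-XL-U50 one — 1024 dimensions per
residue — but any dimensionality is accepted; the synthetic generator uses
small dimensions for desk-scale work.  The language model itself is never
run here: embeddings are either precomputed files or synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import h5py
import numpy as np

from .seqio import ProteinRecord

DEFAULT_EMBED_DIM = 1024


@dataclass
class EmbeddingMatrix:
    """A (p, d) array of per-residue embeddings for one protein."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 2:
            raise ValueError(f"{self.protein_id!r}: embeddings must be 2D")
        if not np.isfinite(self.values).all():
            raise ValueError(f"{self.protein_id!r}: embeddings contain non-finite values")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def save_embeddings(matrices: Mapping[str, EmbeddingMatrix], path) -> None:
    with h5py.File(path, "w") as fh:
        for pid, mat in matrices.items():
            fh.create_dataset(pid, data=mat.values)


def load_embeddings(path, ids: Sequence[str],
                    records: Optional[Sequence[ProteinRecord]] = None
                    ) -> dict[str, EmbeddingMatrix]:
    """Load embeddings for `ids`; validates row counts against `records`."""
    lengths = {r.id: len(r) for r in records} if records is not None else {}
    out: dict[str, EmbeddingMatrix] = {}
    with h5py.File(path, "r") as fh:
        missing = [pid for pid in ids if pid not in fh]
        if missing:
            raise KeyError(f"embedding container {path} is missing ids: {missing}")
        for pid in ids:
            mat = EmbeddingMatrix(protein_id=pid, values=fh[pid][()])
            if pid in lengths and mat.length != lengths[pid]:
                raise ValueError(
                    f"{pid!r}: embedding has {mat.length} rows but the sequence "
                    f"has {lengths[pid]} residues"
                )
            out[pid] = mat
    return out
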