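"""Sequence, label and prediction I/O for secondary-structure prediction.

Defines the DSSP8 / DSSP3 label alphabets, the eight-to-three-state
reduction, and readers/writers for FASTA sequences, labeled CSV datasets
and per-residue prediction tables.

DSSP assigns one of eight states per residue from backbone hydrogen-bond
patterns: 3-helix (G), alpha-helix (H), 5-helix (I), hydrogen-bonded turn
(T), isolated beta-bridge (B), extended strand (E), bend (S) and coil (C).
The reduced three-state scheme groups these into helix (H), strand (E) and
loop (C) via G/H/I -> H, E/B -> E, S/T/C -> C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class Alphabet:
    """Ordered label alphabet with a bijective symbol <-> code map."""

    symbols: str

    def __len__(self) -> int:
        return len(self.symbols)

    def encode(self, labels: str) -> np.ndarray:
        codes = np.empty(len(labels), dtype=np.int64)
        for i, ch in enumerate(labels):
            idx = self.symbols.find(ch)
            if idx < 0:
                raise ValueError(
                    f"unknown symbol {ch!r} at position {i}; alphabet is {self.symbols!r}"
                )
            codes[i] = idx
        return codes

    def decode(self, codes: Sequence[int]) -> str:
        out = []
        for c in codes:
            if not 0 <= int(c) < len(self.symbols):
                raise ValueError(f"code {c} outside alphabet {self.symbols!r}")
            out.append(self.symbols[int(c)])
        return "".join(out)


DSSP8 = Alphabet("GHITBESC")
DSSP3 = Alphabet("HEC")

# General reduction: G/H/I -> H, E/B -> E, S/T/C -> C.
_REDUCTION = {"G": "H", "H": "H", "I": "H",
              "E": "E", "B": "E",
              "S": "C", "T": "C", "C": "C"}


def reduce_dssp8_to_dssp3(labels8: str) -> str:
    """Reduce an eight-state DSSP string to the three-state scheme."""
    try:
        return "".join(_REDUCTION[ch] for ch in labels8)
    except KeyError as exc:
        raise ValueError(f"unknown DSSP8 symbol {exc.args[0]!r}") from None


def encode_labels(labels: str, alphabet: Alphabet) -> np.ndarray:
    """Integer-encode a label string; inverse of ``alphabet.decode``."""
    return alphabet.encode(labels)


def decode_labels(codes: Sequence[int], alphabet: Alphabet) -> str:
    return alphabet.decode(codes)


@dataclass
class ProteinRecord:
    """One protein: identifier, sequence, optional DSSP labels."""

    id: str
    sequence: str
    dssp8: Optional[str] = None
    dssp3: Optional[str] = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValueError(f"record {self.id!r}: invalid residues {sorted(bad)}")
        for name, labels, alphabet in (("dssp8", self.dssp8, DSSP8),
                                       ("dssp3", self.dssp3, DSSP3)):
            if labels is None:
                continue
            if len(labels) != len(self.sequence):
                raise ValueError(
                    f"record {self.id!r}: {name} length {len(labels)} != "
                    f"sequence length {len(self.sequence)}"
                )
            alphabet.encode(labels)  # raises on unknown symbols

    def __len__(self) -> int:
        return len(self.sequence)


class ParseError(ValueError):
    pass


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein sequences; uppercased, non-standard letters mapped to X."""
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not entry.id:
            raise ParseError(f"{path}: entry with empty header")
        if not seq:
            raise ParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        seq = "".join(ch if ch in _VALID_RESIDUES else "X" for ch in seq)
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    return records


def write_fasta(records: Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


_CSV_REQUIRED = ("id", "sequence", "dssp8")


def read_dataset_csv(path) -> list[ProteinRecord]:
    """Read a labeled dataset (columns id, sequence, dssp8[, dssp3]).

    Rows that violate the length/alphabet invariants are rejected with the
    offending row index in the message.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    has3 = "dssp3" in df.columns
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(ProteinRecord(
                id=row["id"],
                sequence=row["sequence"],
                dssp8=row["dssp8"] or None,
                dssp3=(row["dssp3"] or None) if has3 else None,
            ))
        except ValueError as exc:
            raise ParseError(f"{path}: row {idx}: {exc}") from exc
    return records


def write_dataset_csv(records: Sequence[ProteinRecord], path) -> None:
    pd.DataFrame(
        [{"id": r.id, "sequence": r.sequence,
          "dssp8": r.dssp8 or "", "dssp3": r.dssp3 or ""} for r in records]
    ).to_csv(path, index=False)


def write_predictions(records: Sequence[ProteinRecord],
                      probabilities: Sequence[np.ndarray],
                      path, alphabet: Alphabet) -> None:
    """Write a per-residue prediction table (TSV).

    Columns: id, position (1-based), residue, predicted label, one
    probability column per class in alphabet order.
    """
    if len(records) != len(probabilities):
        raise ValueError("records and probability matrices differ in count")
    rows = []
    for rec, probs in zip(records, probabilities):
        probs = np.asarray(probs)
        if probs.shape != (len(rec), len(alphabet)):
            raise ValueError(
                f"record {rec.id!r}: probabilities shape {probs.shape} does not "
                f"match (length {len(rec)}, {len(alphabet)} classes)"
            )
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-5):
            raise ValueError(f"record {rec.id!r}: probability rows must sum to 1")
        pred = alphabet.decode(probs.argmax(axis=1))
        for i, (aa, lab) in enumerate(zip(rec.sequence, pred)):
            row = {"id": rec.id, "position": i + 1, "residue": aa, "label": lab}
            for k, sym in enumerate(alphabet.symbols):
                row[f"p_{sym}"] = probs[i, k]
            rows.append(row)
    cols = ["id", "position", "residue", "label"] + [f"p_{s}" for s in alphabet.symbols]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_predictions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str})
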