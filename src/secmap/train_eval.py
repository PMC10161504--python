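"""Training loop and evaluation statistics.

Training minimizes per-residue cross-entropy with Adam under a
cosine-annealed learning rate, re-cropping every sequence to a fixed
window each epoch (memory control on the quadratic pairwise feature, plus
an augmentation effect).  Evaluation reports per-sequence-averaged
accuracy, residue-pooled macro precision/recall/F1, the multiclass
Matthews correlation coefficient, and paired mean-difference confidence
intervals across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix, matthews_corrcoef, \
    precision_recall_fscore_support

from ._nn import autograd as ag
from ._nn.autograd import Tensor
from ._nn.layers import Adam
from .embeddings import EmbeddingMatrix
from .network import SecondaryStructureNet, external_similarity_stack
from .pairwise_encoder import ModelConfig
from .seqio import DSSP3, DSSP8, Alphabet, ProteinRecord


@dataclass
class TrainConfig:
    batch_size: int = 2
    epochs: int = 10
    crop_len: int = 256
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.crop_len < 1 or self.epochs < 0:
            raise ValueError("batch_size, crop_len must be >= 1; epochs >= 0")


@dataclass
class TrainLog:
    epoch_losses: list = field(default_factory=list)
    epoch_lrs: list = field(default_factory=list)
    parameter_counts: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class EvalReport:
    per_dataset_accuracy: dict
    precision: float
    recall: float
    f1: float
    mcc: float
    mean_diff: Optional[float] = None
    ci95: Optional[tuple] = None


def random_crop(record: ProteinRecord, embedding: EmbeddingMatrix,
                crop_len: int, rng: np.random.Generator
                ) -> tuple[ProteinRecord, EmbeddingMatrix]:
    """Crop record+embedding to a uniformly chosen window of crop_len.

    Sequences at or below crop_len pass through unchanged.  Sequence,
    labels and embedding rows are cropped identically.
    """
    p = len(record)
    if embedding.length != p:
        raise ValueError(
            f"{record.id!r}: embedding rows {embedding.length} != length {p}")
    if p <= crop_len:
        return record, embedding
    start = int(rng.integers(0, p - crop_len + 1))
    stop = start + crop_len
    cropped = ProteinRecord(
        id=record.id,
        sequence=record.sequence[start:stop],
        dssp8=record.dssp8[start:stop] if record.dssp8 else None,
        dssp3=record.dssp3[start:stop] if record.dssp3 else None,
    )
    emb = EmbeddingMatrix(protein_id=embedding.protein_id,
                          values=embedding.values[start:stop])
    return cropped, emb


def _labels_for(record: ProteinRecord, n_classes: int) -> str:
    if n_classes == 8:
        if record.dssp8 is None:
            raise ValueError(f"{record.id!r}: no DSSP8 labels")
        return record.dssp8
    if record.dssp3 is None:
        raise ValueError(f"{record.id!r}: no DSSP3 labels")
    return record.dssp3


def alphabet_for(n_classes: int) -> Alphabet:
    return DSSP8 if n_classes == 8 else DSSP3


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean per-residue cross-entropy from (p, K) logits."""
    p, k = logits.shape
    onehot = np.zeros((p, k), dtype=np.float32)
    onehot[np.arange(p), targets] = 1.0
    logp = ag.log_softmax(logits, axis=-1)
    return -ag.tsum(logp * Tensor(onehot)) * (1.0 / p)


def _external_stacks(records, embeddings, n_channels: int):
    return {r.id: external_similarity_stack(embeddings[r.id].values, n_channels)
            for r in records}


def train(dataset: Sequence[ProteinRecord],
          embeddings: dict[str, EmbeddingMatrix],
          model_config: ModelConfig,
          train_config: TrainConfig,
          external_stack_channels: int = 1,
          ) -> tuple[SecondaryStructureNet, TrainLog]:
    """Train a model on labeled records; returns (model, log).

    All randomness (init, shuffling, crops) derives from
    train_config.seed, so a repeat run reproduces the loss curve exactly.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    alphabet = alphabet_for(model_config.n_classes)
    for rec in dataset:
        alphabet.encode(_labels_for(rec, model_config.n_classes))
    rng = np.random.default_rng(train_config.seed)
    model = SecondaryStructureNet(model_config, rng,
                                  external_stack_channels=external_stack_channels)
    total_steps = max(1, int(np.ceil(len(dataset) / train_config.batch_size))
                      * train_config.epochs)
    opt = Adam(model.parameters(), lr=train_config.learning_rate,
               total_steps=total_steps,
               weight_decay=train_config.weight_decay)
    log = TrainLog(seed=train_config.seed,
                   parameter_counts=model.component_parameter_counts())
    ext = model_config.variant == "external_attention"

    for _epoch in range(train_config.epochs):
        order = rng.permutation(len(dataset))
        epoch_loss, n_seqs = 0.0, 0
        for b0 in range(0, len(order), train_config.batch_size):
            batch = order[b0:b0 + train_config.batch_size]
            opt.zero_grad()
            losses = []
            for idx in batch:
                rec, emb = random_crop(dataset[idx], embeddings[dataset[idx].id],
                                       train_config.crop_len, rng)
                targets = alphabet.encode(_labels_for(rec, model_config.n_classes))
                stack = None
                if ext:
                    arr = external_similarity_stack(emb.values,
                                                    external_stack_channels)
                    stack = Tensor(np.transpose(arr, (2, 0, 1)))
                logits = model(Tensor(emb.values), stack)
                losses.append(cross_entropy(logits, targets))
            loss = losses[0] if len(losses) == 1 else (
                ag.concat([ag.reshape(l, (1,)) for l in losses], axis=0).mean())
            value = float(loss.numpy())
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite training loss ({value}) at epoch {_epoch}")
            loss.backward()
            opt.step()
            epoch_loss += value * len(batch)
            n_seqs += len(batch)
        log.epoch_losses.append(epoch_loss / n_seqs)
        log.epoch_lrs.append(float(opt.lr))
    return model, log


def predict_sequence(record: ProteinRecord, embedding: EmbeddingMatrix,
                     model: SecondaryStructureNet,
                     external_stack: Optional[np.ndarray] = None
                     ) -> tuple[str, np.ndarray]:
    """Predict per-residue labels and probabilities for one protein."""
    if embedding.length != len(record):
        raise ValueError(
            f"{record.id!r}: embedding rows {embedding.length} != "
            f"sequence length {len(record)}")
    cfg = model.config
    if cfg.variant == "external_attention" and external_stack is None:
        external_stack = external_similarity_stack(embedding.values)
    probs = model.predict_proba(embedding.values, external_stack)
    labels = alphabet_for(cfg.n_classes).decode(probs.argmax(axis=1))
    return labels, probs


# ---- evaluation statistics -------------------------------------------------


def dataset_accuracy(predictions: Sequence[str], references: Sequence[str]) -> float:
    """Mean over sequences of per-sequence residue accuracy.

    This is sequence-averaged, not residue-pooled: short and long proteins
    weigh equally.
    """
    if not predictions:
        raise ValueError("empty evaluation set")
    if len(predictions) != len(references):
        raise ValueError("predictions and references differ in count")
    accs = []
    for pred, ref in zip(predictions, references):
        if len(pred) != len(ref):
            raise ValueError(f"length mismatch: {len(pred)} vs {len(ref)}")
        accs.append(np.mean([a == b for a, b in zip(pred, ref)]))
    return float(np.mean(accs))


def _pool(predictions, references, alphabet: Alphabet):
    y_pred, y_true = [], []
    for pred, ref in zip(predictions, references):
        if len(pred) != len(ref):
            raise ValueError(f"length mismatch: {len(pred)} vs {len(ref)}")
        y_pred.extend(alphabet.encode(pred))
        y_true.extend(alphabet.encode(ref))
    return np.asarray(y_true), np.asarray(y_pred)


def class_metrics(predictions: Sequence[str], references: Sequence[str],
                  alphabet: Alphabet) -> tuple[float, float, float]:
    """Residue-pooled macro precision, recall and F1 over all K classes.

    Classes absent from both predictions and references still count in the
    macro average (zero-division treated as 0).
    """
    if not predictions:
        raise ValueError("empty evaluation set")
    y_true, y_pred = _pool(predictions, references, alphabet)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(range(len(alphabet))),
        average="macro", zero_division=0)
    return float(prec), float(rec), float(f1)


def mcc(predictions: Sequence[str], references: Sequence[str],
        alphabet: Alphabet) -> float:
    """Multiclass Matthews correlation coefficient on pooled residues.

    Degenerate inputs (a single class on both sides) are defined as 0.
    """
    if not predictions:
        raise ValueError("empty evaluation set")
    y_true, y_pred = _pool(predictions, references, alphabet)
    if len(set(y_true) | set(y_pred)) < 2:
        return 0.0
    return float(matthews_corrcoef(y_true, y_pred))


def confusion(predictions: Sequence[str], references: Sequence[str],
              alphabet: Alphabet) -> np.ndarray:
    y_true, y_pred = _pool(predictions, references, alphabet)
    return confusion_matrix(y_true, y_pred, labels=list(range(len(alphabet))))


def mean_difference_ci(our_acc: Sequence[float], other_acc: Sequence[float]
                       ) -> tuple[float, tuple[float, float]]:
    """Paired mean accuracy difference with a 95% t confidence interval.

    The interval uses the t distribution with n-1 degrees of freedom over
    the per-dataset paired differences; identical lists give a degenerate
    zero-width interval.
    """
    ours, others = np.asarray(our_acc, float), np.asarray(other_acc, float)
    if ours.shape != others.shape or ours.ndim != 1:
        raise ValueError("paired accuracy lists must be 1D of equal length")
    n = ours.size
    if n < 2:
        raise ValueError("need at least two paired datasets")
    diff = ours - others
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        return mean, (mean, mean)
    half = float(stats.t.ppf(0.975, df=n - 1)) * sd / np.sqrt(n)
    return mean, (mean - half, mean + half)


def evaluate(predictions: Sequence[str],
             references: Sequence[str],
             alphabet: Alphabet,
             dataset_names: Optional[Sequence[str]] = None) -> EvalReport:
    """Full report: per-dataset accuracies + pooled macro metrics + MCC."""
    if dataset_names is None:
        dataset_names = ["all"] * len(predictions)
    per_ds: dict[str, list] = {}
    for pred, ref, name in zip(predictions, references, dataset_names):
        per_ds.setdefault(name, []).append((pred, ref))
    acc = {name: dataset_accuracy([p for p, _ in pairs], [r for _, r in pairs])
           for name, pairs in per_ds.items()}
    prec, rec, f1 = class_metrics(predictions, references, alphabet)
    return EvalReport(per_dataset_accuracy=acc, precision=prec, recall=rec,
                      f1=f1, mcc=mcc(predictions, references, alphabet))
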