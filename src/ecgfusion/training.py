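"""Training protocol: splits, chunked batches, schedules, the train loop.

Records are split 70/15/15 into train/validation/test by a seeded shuffle;
the whole protocol is repeated with five seeds (non-exhaustive cross
validation).  Because every batch must be a rectangular tensor, records are
grouped into chunks sharing the same QRS-segment count; each batch samples a
chunk according to the empirical chunk distribution and takes the whole
chunk if it holds at most 256 records, else 256 sampled without replacement.

Optimization is Adam with cross-entropy loss, starting at lr 0.001, halved
after 50 epochs without a new best training accuracy (counted from the last
improvement or reduction, floored at 1e-6), with early stopping after 250
epochs without a new best validation accuracy; the best-validation weights
are retained.  An epoch is 10 batches.  Accuracy is the monitored quantity
for both schedulers by default (loss monitoring is available as an option).
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np

from .model import FusionModel
from .nn import softmax_cross_entropy

DEFAULT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclasses.dataclass
class RecordFeatures:
    """Per-record model inputs produced by the feature pipeline."""

    record_id: str
    label: int
    raw: np.ndarray | None = None  # (12, 5000)
    raw_entropy: np.ndarray | None = None  # (156,)
    qrs: np.ndarray | None = None  # (n_segments, 12, 100)
    qrs_entropy: np.ndarray | None = None  # (n_segments, 156)
    bpm: float = 0.0

    @property
    def n_segments(self) -> int:
        if self.qrs is not None:
            return self.qrs.shape[0]
        if self.qrs_entropy is not None:
            return self.qrs_entropy.shape[0]
        return 0


@dataclasses.dataclass
class SplitSpec:
    fractions: tuple[float, float, float]
    seed: int
    assignment: dict[str, str]  # record_id -> {"train", "val", "test"}

    def ids(self, part: str) -> list[str]:
        return [r for r, p in self.assignment.items() if p == part]


def split_dataset(
    record_ids: Sequence[str],
    seed: int,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
) -> SplitSpec:
    """Seeded shuffle then proportional cut into train/val/test."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = list(record_ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 records to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(len(ids) * fractions[0])
    n_val = int(len(ids) * fractions[1])
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        part = ("train" if rank < n_train
                else "val" if rank < n_train + n_val else "test")
        assignment[ids[idx]] = part
    return SplitSpec(tuple(fractions), seed, assignment)


@dataclasses.dataclass
class ChunkIndex:
    """Records grouped by QRS-segment count, with the empirical distribution."""

    chunks: dict[int, list[RecordFeatures]]
    distribution: dict[int, float]


def build_chunks(dataset: Sequence[RecordFeatures]) -> ChunkIndex:
    if not dataset:
        raise ValueError("empty dataset")
    chunks: dict[int, list[RecordFeatures]] = {}
    for rec in dataset:
        chunks.setdefault(rec.n_segments, []).append(rec)
    total = len(dataset)
    distribution = {k: len(v) / total for k, v in chunks.items()}
    return ChunkIndex(chunks, distribution)


def draw_batch(
    index: ChunkIndex, rng: np.random.Generator, batch_size: int = 256
) -> list[RecordFeatures]:
    """Sample a QRS count from the distribution, then records from its chunk."""
    counts = sorted(index.distribution)
    probs = np.array([index.distribution[c] for c in counts])
    chosen = counts[int(rng.choice(len(counts), p=probs))]
    chunk = index.chunks[chosen]
    if len(chunk) <= batch_size:
        return list(chunk)
    picks = rng.choice(len(chunk), size=batch_size, replace=False)
    return [chunk[i] for i in picks]


def assemble_batch(
    records: Sequence[RecordFeatures], modules: Sequence[str]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Stack per-record inputs into rectangular arrays for the model."""
    batch: dict[str, np.ndarray] = {}
    for name in modules:
        parts = [getattr(r, name) for r in records]
        if any(p is None for p in parts):
            raise ValueError(f"records lack features for module {name!r}")
        batch[name] = np.stack(parts)
    labels = np.array([r.label for r in records], dtype=int)
    return batch, labels


@dataclasses.dataclass
class LrScheduler:
    """Halve the learning rate after ``patience`` stagnant epochs.

    The stagnation counter restarts at every improvement of the monitored
    training metric and at every reduction; the rate never drops below
    ``floor``.
    """

    lr: float = 1e-3
    patience: int = 50
    floor: float = 1e-6
    _best: float = -np.inf
    _stagnant: int = 0

    def update(self, metric: float) -> float:
        if metric > self._best:
            self._best = metric
            self._stagnant = 0
        else:
            self._stagnant += 1
            if self._stagnant >= self.patience:
                self.lr = max(self.lr / 2.0, self.floor)
                self._stagnant = 0
        return self.lr


def lr_step(stagnant_epochs: int, current_lr: float, patience: int = 50,
            floor: float = 1e-6) -> float:
    """Stateless form of the halving rule for a given stagnation count."""
    if stagnant_epochs >= patience:
        return max(current_lr / 2.0, floor)
    return current_lr


@dataclasses.dataclass
class TrainConfig:
    max_epochs: int = 10_000
    early_stop_patience: int = 250
    lr_init: float = 1e-3
    lr_halve_patience: int = 50
    lr_floor: float = 1e-6
    batches_per_epoch: int = 10
    batch_size: int = 256
    seed: int = 0
    monitor: str = "accuracy"  # or "loss"

    def __post_init__(self) -> None:
        if self.lr_floor >= self.lr_init:
            raise ValueError("lr_floor must be below lr_init")
        if min(self.max_epochs, self.early_stop_patience, self.batch_size,
               self.batches_per_epoch) <= 0:
            raise ValueError("all protocol sizes must be positive")


@dataclasses.dataclass
class History:
    epochs: list[dict] = dataclasses.field(default_factory=list)
    best_val_metric: float = -np.inf
    best_epoch: int = 0
    stopped_early: bool = False

    def to_csv(self, path: str) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["epoch", "lr", "train_acc", "train_loss",
                               "val_acc", "val_loss"])
            writer.writeheader()
            writer.writerows(self.epochs)


def evaluate_dataset(
    model: FusionModel, records: Sequence[RecordFeatures]
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Accuracy, mean loss, class scores and labels over a record list.

    Records are grouped by QRS count so every forward pass is rectangular;
    outputs are reassembled in the input order.
    """
    modules = model.config.enabled
    scores = np.zeros((len(records), model.config.n_classes))
    labels = np.array([r.label for r in records], dtype=int)
    by_count: dict[int, list[int]] = {}
    for i, rec in enumerate(records):
        by_count.setdefault(rec.n_segments, []).append(i)
    for idxs in by_count.values():
        batch, _ = assemble_batch([records[i] for i in idxs], modules)
        scores[idxs] = model.forward(batch)
    loss, _ = softmax_cross_entropy(scores, labels)
    acc = float(np.mean(np.argmax(scores, axis=1) == labels))
    return acc, loss, scores, labels


class DivergenceError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


def train_model(
    model: FusionModel,
    train_records: Sequence[RecordFeatures],
    val_records: Sequence[RecordFeatures],
    cfg: TrainConfig,
    verbose: bool = False,
) -> History:
    """Run the full optimization protocol; the model ends at its best-
    validation checkpoint."""
    rng = np.random.default_rng(cfg.seed)
    chunks = build_chunks(list(train_records))
    opt = model.make_optimizer(cfg.lr_init)
    sched = LrScheduler(cfg.lr_init, cfg.lr_halve_patience, cfg.lr_floor)
    history = History()
    best_state = model.state_dict()
    sign = 1.0 if cfg.monitor == "accuracy" else -1.0

    for epoch in range(1, cfg.max_epochs + 1):
        correct = total = 0
        losses = []
        for _ in range(cfg.batches_per_epoch):
            recs = draw_batch(chunks, rng, cfg.batch_size)
            batch, labels = assemble_batch(recs, model.config.enabled)
            scores = model.forward(batch)
            loss, dscores = softmax_cross_entropy(scores, labels)
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dscores)
            opt.step()
            losses.append(loss)
            correct += int(np.sum(np.argmax(scores, axis=1) == labels))
            total += len(labels)
        train_acc = correct / total
        train_loss = float(np.mean(losses))
        train_metric = train_acc if cfg.monitor == "accuracy" else -train_loss
        opt.lr = sched.update(train_metric)

        val_acc, val_loss, _, _ = evaluate_dataset(model, val_records)
        val_metric = sign * (val_acc if cfg.monitor == "accuracy" else val_loss)
        history.epochs.append({
            "epoch": epoch, "lr": opt.lr, "train_acc": train_acc,
            "train_loss": train_loss, "val_acc": val_acc, "val_loss": val_loss,
        })
        if val_metric > history.best_val_metric:
            history.best_val_metric = val_metric
            history.best_epoch = epoch
            best_state = model.state_dict()
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch:5d} lr {opt.lr:.2e} "
                  f"train {train_acc:.3f} val {val_acc:.3f}")
        if epoch - history.best_epoch >= cfg.early_stop_patience:
            history.stopped_early = True
            break

    model.load_state(best_state)
    return history


def train_with_restarts(
    model_factory: Callable[[int], FusionModel],
    train_records: Sequence[RecordFeatures],
    val_records: Sequence[RecordFeatures],
    cfg: TrainConfig,
    restarts: int = 0,
) -> tuple[FusionModel, History]:
    """Optionally retrain fresh networks after early stopping, keeping the
    model with the best validation metric across restarts."""
    best: tuple[FusionModel, History] | None = None
    for attempt in range(restarts + 1):
        model = model_factory(attempt)
        run_cfg = dataclasses.replace(cfg, seed=cfg.seed + attempt)
        hist = train_model(model, train_records, val_records, run_cfg)
        if best is None or hist.best_val_metric > best[1].best_val_metric:
            best = (model, hist)
    assert best is not None
    return best


def audit_no_overlap(split: SplitSpec) -> bool:
    """Verify the split is a partition (no record in two parts)."""
    parts = [set(split.ids(p)) for p in ("train", "val", "test")]
    total = sum(len(p) for p in parts)
    return len(set().union(*parts)) == total
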