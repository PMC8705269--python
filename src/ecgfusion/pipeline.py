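"""End-to-end pipeline: detect -> segment -> entropy features -> train -> evaluate.

`prepare_features` turns one record into the model inputs (raw signal, raw
entropy vector, QRS beat stack, per-beat entropy vectors), computing only
what the enabled modules need; records whose consensus finds fewer than
three beats cannot yield a center segment and are dropped (counted by the
caller).  `run_experiment` repeats split/train/evaluate over several split
seeds and aggregates the test metrics.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .consensus import DegenerateRecordError, compute_consensus
from .data_io import EcgRecord, synthetic_dataset
from .detectors import DetectorBank
from .entropy import EntropyConfig, feature_vector
from .evaluation import EvalReport, aggregate_cv, evaluate_predictions
from .model import FusionModel, ModuleConfig
from .segmentation import segment_record
from .training import (
    RecordFeatures,
    TrainConfig,
    evaluate_dataset,
    split_dataset,
    train_model,
)

logger = logging.getLogger(__name__)


def prepare_features(
    record: EcgRecord,
    label: int,
    modules: Sequence[str] = ("raw", "qrs", "qrs_entropy"),
    bank: DetectorBank | None = None,
    entropy_cfg: EntropyConfig | None = None,
) -> RecordFeatures | None:
    """Compute the model inputs one record needs; None if unusable.

    A record is unusable when beat consensus degenerates or segmentation
    leaves no interior beat (fewer than 3 consensus peaks).
    """
    entropy_cfg = entropy_cfg or EntropyConfig()
    feats = RecordFeatures(record.record_id, label)
    need_segments = "qrs" in modules or "qrs_entropy" in modules
    try:
        consensus = compute_consensus(record, bank)
    except DegenerateRecordError:
        logger.info("record %s: degenerate consensus, dropped", record.record_id)
        return None
    feats.bpm = consensus.bpm
    if need_segments:
        seg = segment_record(record, consensus)
        if not seg.usable or seg.n_segments == 0:
            logger.info("record %s: no usable segments, dropped", record.record_id)
            return None
        if "qrs" in modules:
            feats.qrs = seg.beats_array().astype(np.float32)
        if "qrs_entropy" in modules:
            feats.qrs_entropy = np.stack(
                [feature_vector(s.beat, entropy_cfg) for s in seg.segments]
            ).astype(np.float32)
    if "raw" in modules:
        feats.raw = record.signal.astype(np.float32)
    if "raw_entropy" in modules:
        feats.raw_entropy = feature_vector(record.signal, entropy_cfg).astype(np.float32)
    return feats


def prepare_dataset(
    records: Sequence[tuple[EcgRecord, int]],
    modules: Sequence[str],
    bank: DetectorBank | None = None,
    entropy_cfg: EntropyConfig | None = None,
) -> tuple[list[RecordFeatures], int]:
    """Feature-extract a labeled record list; returns (features, n_dropped)."""
    bank = bank or DetectorBank.default()
    out: list[RecordFeatures] = []
    dropped = 0
    for record, label in records:
        feats = prepare_features(record, label, modules, bank, entropy_cfg)
        if feats is None:
            dropped += 1
        else:
            out.append(feats)
    if dropped:
        logger.info("dropped %d/%d records during feature extraction",
                    dropped, len(records))
    return out, dropped


@dataclasses.dataclass
class ExperimentResult:
    report: EvalReport
    histories: list
    per_seed: list[dict[str, float]]


def run_experiment(
    dataset: Sequence[RecordFeatures],
    module_config: ModuleConfig,
    train_cfg: TrainConfig,
    split_seeds: Sequence[int] = (1, 2, 3, 4, 5),
) -> ExperimentResult:
    """Split/train/evaluate once per seed; aggregate the test metrics."""
    by_id = {r.record_id: r for r in dataset}
    per_seed = []
    histories = []
    for seed in split_seeds:
        split = split_dataset(list(by_id), seed=seed)
        train = [by_id[i] for i in split.ids("train")]
        val = [by_id[i] for i in split.ids("val")]
        test = [by_id[i] for i in split.ids("test")]
        cfg = dataclasses.replace(train_cfg, seed=train_cfg.seed + seed)
        model = FusionModel(dataclasses.replace(
            module_config, seed=module_config.seed + seed))
        hist = train_model(model, train, val, cfg)
        _, _, scores, labels = evaluate_dataset(model, test)
        per_seed.append(evaluate_predictions(scores, labels,
                                             module_config.n_classes))
        histories.append(hist)
    return ExperimentResult(aggregate_cv(per_seed), histories, per_seed)


def run_synthetic_experiment(
    n_records: int = 200,
    n_classes: int = 2,
    modules: Sequence[str] = ("raw", "qrs", "qrs_entropy"),
    noise_sd: float = 0.02,
    seed: int = 0,
    split_seeds: Sequence[int] = (1, 2, 3, 4, 5),
    train_cfg: TrainConfig | None = None,
) -> ExperimentResult:
    """Generate a synthetic cohort and run the full pipeline on it."""
    data = synthetic_dataset(n_records, n_classes=n_classes, seed=seed,
                             noise_sd=noise_sd)
    labeled = [(rec, rec.binary_label if n_classes == 2 else
                list(("NORM", "CD", "STTC", "MI", "HYP")).index(rec.superclass))
               for rec, _ in data]
    features, _ = prepare_dataset(labeled, modules)
    mc = ModuleConfig(enabled=tuple(modules), n_classes=n_classes, seed=seed)
    tc = train_cfg or TrainConfig(max_epochs=100, seed=seed)
    return run_experiment(features, mc, tc, split_seeds)
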