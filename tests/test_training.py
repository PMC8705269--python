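import dataclasses

import numpy as np
import pytest

from ecgfusion.model import FusionModel, ModuleConfig
from ecgfusion.training import (
    LrScheduler,
    RecordFeatures,
    TrainConfig,
    assemble_batch,
    audit_no_overlap,
    build_chunks,
    draw_batch,
    lr_step,
    split_dataset,
    train_model,
)


def _fake(rid, label, n_segments):
    return RecordFeatures(rid, label, qrs=np.zeros((n_segments, 1, 1)))


class TestSplit:
    def test_70_15_15(self):
        ids = [f"r{i}" for i in range(100)]
        split = split_dataset(ids, seed=1)
        assert len(split.ids("train")) == 70
        assert len(split.ids("val")) == 15
        assert len(split.ids("test")) == 15

    def test_deterministic(self):
        ids = [f"r{i}" for i in range(50)]
        assert split_dataset(ids, seed=3).assignment == \
            split_dataset(ids, seed=3).assignment

    def test_five_seeds_distinct(self):
        ids = [f"r{i}" for i in range(100)]
        assignments = [tuple(sorted(split_dataset(ids, seed=s).assignment.items()))
                       for s in range(1, 6)]
        assert len(set(assignments)) == 5

    def test_partition(self):
        split = split_dataset([f"r{i}" for i in range(40)], seed=2)
        assert audit_no_overlap(split)

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            split_dataset(["a"] * 5, seed=1)

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            split_dataset([f"r{i}" for i in range(20)], 1, (0.5, 0.3, 0.3))


class TestChunks:
    def test_distribution(self):
        data = [_fake(f"a{i}", 0, 8) for i in range(30)]
        data += [_fake(f"b{i}", 0, 9) for i in range(10)]
        idx = build_chunks(data)
        assert set(idx.chunks) == {8, 9}
        assert idx.distribution == {8: 0.75, 9: 0.25}
        assert sum(len(c) for c in idx.chunks.values()) == 40

    def test_single_chunk(self):
        idx = build_chunks([_fake(f"r{i}", 0, 5) for i in range(7)])
        assert list(idx.chunks) == [5]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_chunks([])


class TestDrawBatch:
    def test_small_chunk_returned_whole(self):
        idx = build_chunks([_fake(f"r{i}", 0, 8) for i in range(100)])
        batch = draw_batch(idx, np.random.default_rng(0))
        assert len(batch) == 100

    def test_large_chunk_capped_at_256(self):
        idx = build_chunks([_fake(f"r{i}", 0, 8) for i in range(300)])
        batch = draw_batch(idx, np.random.default_rng(0))
        assert len(batch) == 256
        assert len({r.record_id for r in batch}) == 256  # without replacement

    def test_batches_homogeneous_in_qrs_count(self):
        data = [_fake(f"r{i}", 0, 5 + i % 4) for i in range(60)]
        idx = build_chunks(data)
        rng = np.random.default_rng(1)
        for _ in range(50):
            batch = draw_batch(idx, rng)
            assert len({r.n_segments for r in batch}) == 1

    def test_chunk_frequencies_match_distribution(self):
        """Chunk selection follows the empirical QRS-count distribution."""
        data = [_fake(f"a{i}", 0, 8) for i in range(60)]
        data += [_fake(f"b{i}", 0, 9) for i in range(30)]
        data += [_fake(f"c{i}", 0, 10) for i in range(10)]
        idx = build_chunks(data)
        rng = np.random.default_rng(123)
        n_draws = 10_000
        hits = {8: 0, 9: 0, 10: 0}
        for _ in range(n_draws):
            hits[draw_batch(idx, rng)[0].n_segments] += 1
        for count, p in idx.distribution.items():
            se = np.sqrt(p * (1 - p) / n_draws)
            assert abs(hits[count] / n_draws - p) < 3 * se


class TestSchedulers:
    def test_halves_after_50_stagnant_epochs(self):
        sched = LrScheduler(lr=1e-3, patience=50)
        sched.update(0.5)  # initial best
        for _ in range(49):
            assert sched.update(0.5) == 1e-3
        assert sched.update(0.5) == 5e-4

    def test_improvement_resets_counter(self):
        sched = LrScheduler(lr=1e-3, patience=50)
        sched.update(0.5)
        for _ in range(49):
            sched.update(0.5)
        sched.update(0.6)  # improvement at epoch 49 of stagnation
        assert sched.lr == 1e-3
        for _ in range(49):
            assert sched.update(0.6) == 1e-3
        assert sched.update(0.6) == 5e-4

    def test_floor(self):
        sched = LrScheduler(lr=2e-6, patience=1)
        sched.update(1.0)
        assert sched.update(1.0) == 1e-6
        assert sched.update(1.0) == 1e-6  # no further reduction

    def test_stateless_rule(self):
        assert lr_step(50, 1e-3) == 5e-4
        assert lr_step(49, 1e-3) == 1e-3
        assert lr_step(50, 1.5e-6) == 1e-6


class TestTrainConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_floor=0.01, lr_init=0.001)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


def _entropy_toy(n, seed=0, separation=3.0):
    """Linearly separable toy: entropy vectors shifted by the class label."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        label = i % 2
        vec = rng.normal(label * separation, 1.0, 156).astype(np.float32)
        out.append(RecordFeatures(f"t{i}", label, raw_entropy=vec,
                                  qrs=np.zeros((8, 1, 1), dtype=np.float32)))
    return out


class TestTrainLoop:
    def test_learns_separable_toy(self):
        data = _entropy_toy(80)
        model = FusionModel(ModuleConfig(enabled=("raw_entropy",), n_classes=2, seed=0))
        cfg = TrainConfig(max_epochs=80, seed=0)
        hist = train_model(model, data[:60], data[60:], cfg)
        assert hist.best_val_metric >= 0.95

    def test_deterministic_given_seed(self):
        data = _entropy_toy(40)
        losses = []
        for _ in range(2):
            model = FusionModel(ModuleConfig(enabled=("raw_entropy",), n_classes=2, seed=5))
            hist = train_model(model, data[:30], data[30:],
                               TrainConfig(max_epochs=5, seed=5))
            losses.append([e["train_loss"] for e in hist.epochs])
        assert losses[0] == losses[1]

    def test_early_stopping_fires_at_patience_plus_one(self):
        """A frozen model (vanishing learning rate, constant validation
        metric) stops exactly one epoch after the patience window closes."""
        data = _entropy_toy(40)
        model = FusionModel(ModuleConfig(enabled=("raw_entropy",), n_classes=2, seed=1))
        cfg = TrainConfig(max_epochs=400, early_stop_patience=20, seed=1,
                          lr_init=1e-12, lr_floor=1e-13)
        hist = train_model(model, data[:30], data[30:], cfg)
        assert hist.stopped_early
        assert hist.epochs[-1]["epoch"] == 21
        assert len({e["val_acc"] for e in hist.epochs}) == 1

    def test_best_checkpoint_retained(self):
        data = _entropy_toy(60)
        model = FusionModel(ModuleConfig(enabled=("raw_entropy",), n_classes=2, seed=2))
        hist = train_model(model, data[:45], data[45:],
                           TrainConfig(max_epochs=15, seed=2))
        from ecgfusion.training import evaluate_dataset

        acc, _, _, _ = evaluate_dataset(model, data[45:])
        assert acc == pytest.approx(hist.best_val_metric)
        assert hist.best_val_metric == max(e["val_acc"] for e in hist.epochs)

    def test_no_validation_leakage(self):
        """Validation records never appear in any training batch."""
        data = _entropy_toy(40)
        train, val = data[:30], data[30:]
        val_ids = {r.record_id for r in val}
        from ecgfusion.training import build_chunks as bc

        idx = bc(train)
        rng = np.random.default_rng(0)
        for _ in range(100):
            batch = draw_batch(idx, rng)
            assert not val_ids & {r.record_id for r in batch}


def test_assemble_batch_missing_feature():
    recs = [RecordFeatures("a", 0, raw_entropy=np.zeros(156, dtype=np.float32))]
    with pytest.raises(ValueError):
        assemble_batch(recs, ("qrs",))
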