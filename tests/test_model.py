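import numpy as np
import pytest

from ecgfusion.model import (
    FusionModel,
    ModuleConfig,
    QRS_CODE_DIM,
    aggregate_set,
    all_module_combinations,
    build_entropy_encoder,
    build_qrs_single_encoder,
    build_raw_encoder,
    count_weights,
    shape_trace,
)
from ecgfusion.nn import softmax_cross_entropy

RNG = np.random.default_rng(0)


class TestArchitectureArithmetic:
    def test_raw_encoder_pool_lengths(self):
        trace = shape_trace(build_raw_encoder(np.random.default_rng(0)), (12, 5000))
        lengths = [t[1] for t in trace]  # lengths after each layer
        for expected in (1666, 555, 185, 61, 20):
            assert expected in lengths
        assert trace[-2] == (1, 40)   # flatten after kernel-1 conv
        assert trace[-1] == (1, 20)   # final FC

    def test_pre_reduction_flatten_would_be_1920(self):
        trace = shape_trace(build_raw_encoder(np.random.default_rng(0)), (12, 5000))
        c, length = trace[14]  # after the fifth pool, before the k1 conv
        assert (c, length) == (96, 20)
        assert c * length == 1920

    def test_weight_counts(self):
        assert count_weights((1920, 20)) == 38_400
        assert count_weights((40, 20)) == 800
        assert count_weights((96, 2, 1)) == 192
        enc = build_entropy_encoder(156, np.random.default_rng(0))
        assert count_weights(enc.layers[0]) == 3120  # 156 x 20

    def test_qrs_encoder_24_dim(self):
        enc = build_qrs_single_encoder(np.random.default_rng(0))
        assert shape_trace(enc, (12, 100))[-1] == (1, QRS_CODE_DIM)

    def test_qrs_encoder_as_printed_22_dim(self):
        enc = build_qrs_single_encoder(np.random.default_rng(0), as_printed=True)
        assert shape_trace(enc, (12, 100))[-1] == (1, 22)


class TestAggregateSet:
    def test_singleton_identity(self):
        v = RNG.standard_normal(24)
        agg = aggregate_set([v])
        np.testing.assert_array_equal(agg.z_max, v)
        np.testing.assert_array_equal(agg.z_avg, v)
        np.testing.assert_array_equal(agg.z_all, np.concatenate([v, v]))

    def test_zeros_and_ones(self):
        agg = aggregate_set([np.zeros(24), np.ones(24)])
        np.testing.assert_array_equal(agg.z_max, np.ones(24))
        np.testing.assert_array_equal(agg.z_avg, np.full(24, 0.5))
        assert agg.z_all.shape == (48,)

    def test_max_dominates_avg(self):
        for seed in range(5):
            vs = np.random.default_rng(seed).standard_normal((7, 24))
            agg = aggregate_set(vs)
            assert np.all(agg.z_max >= agg.z_avg)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            aggregate_set(np.empty((0, 24)))


class TestEncoders:
    def test_raw_encoder_output_20(self):
        enc = build_raw_encoder(np.random.default_rng(0))
        out = enc.forward(RNG.standard_normal((3, 12, 5000)).astype(np.float32))
        assert out.shape == (3, 20)

    def test_zero_input_finite(self):
        enc = build_raw_encoder(np.random.default_rng(0))
        out = enc.forward(np.zeros((1, 12, 5000), dtype=np.float32))
        assert np.all(np.isfinite(out))

    def test_wrong_channel_count_rejected(self):
        enc = build_raw_encoder(np.random.default_rng(0))
        with pytest.raises(ValueError):
            enc.forward(np.zeros((1, 8, 5000), dtype=np.float32))

    def test_identical_beats_identical_codes(self):
        enc = build_qrs_single_encoder(np.random.default_rng(3))
        beat = RNG.standard_normal((1, 12, 100)).astype(np.float32)
        np.testing.assert_array_equal(enc.forward(beat), enc.forward(beat))


@pytest.fixture(scope="module")
def set_model():
    return FusionModel(ModuleConfig(
        enabled=("qrs", "qrs_entropy"), n_classes=2, seed=1, dtype=np.float64))


class TestSetEncoders:
    def test_permutation_invariant(self, set_model):
        rng = np.random.default_rng(0)
        qrs = rng.standard_normal((2, 9, 12, 100))
        ent = rng.standard_normal((2, 9, 156))
        base = set_model.forward({"qrs": qrs, "qrs_entropy": ent})
        perm = rng.permutation(9)
        out = set_model.forward({"qrs": qrs[:, perm], "qrs_entropy": ent[:, perm]})
        np.testing.assert_allclose(out, base, rtol=1e-10, atol=1e-12)

    def test_duplication_invariant(self, set_model):
        rng = np.random.default_rng(1)
        qrs = rng.standard_normal((1, 5, 12, 100))
        ent = rng.standard_normal((1, 5, 156))
        base = set_model.forward({"qrs": qrs, "qrs_entropy": ent})
        out = set_model.forward({
            "qrs": np.concatenate([qrs, qrs], axis=1),
            "qrs_entropy": np.concatenate([ent, ent], axis=1)})
        np.testing.assert_allclose(out, base, rtol=1e-10, atol=1e-12)

    def test_variable_set_sizes(self, set_model):
        rng = np.random.default_rng(2)
        for s in (4, 8, 26):
            out = set_model.forward({
                "qrs": rng.standard_normal((1, s, 12, 100)),
                "qrs_entropy": rng.standard_normal((1, s, 156))})
            assert out.shape == (1, 2)

    def test_empty_set_rejected(self, set_model):
        with pytest.raises(ValueError):
            set_model.forward({"qrs": np.zeros((1, 0, 12, 100)),
                           "qrs_entropy": np.zeros((1, 0, 156))})


class TestFusion:
    @pytest.mark.parametrize("n_classes", [2, 5, 20])
    def test_all_15_combinations_build_and_run(self, n_classes):
        rng = np.random.default_rng(0)
        batch_full = {
            "raw": rng.standard_normal((2, 12, 5000)).astype(np.float32),
            "raw_entropy": rng.standard_normal((2, 156)).astype(np.float32),
            "qrs": rng.standard_normal((2, 6, 12, 100)).astype(np.float32),
            "qrs_entropy": rng.standard_normal((2, 6, 156)).astype(np.float32),
        }
        combos = all_module_combinations()
        assert len(combos) == 15
        for combo in combos:
            model = FusionModel(ModuleConfig(enabled=combo, n_classes=n_classes))
            assert model.fusion_fc.in_features == 20 * len(combo)
            out = model.forward({k: batch_full[k] for k in combo})
            assert out.shape == (2, n_classes)

    def test_single_module_fc_weight_count(self):
        model = FusionModel(ModuleConfig(enabled=("raw_entropy",), n_classes=2))
        assert count_weights(model.fusion_fc) == 40  # 20 x 2

    def test_missing_module_input_rejected(self):
        model = FusionModel(ModuleConfig(enabled=("raw", "raw_entropy")))
        with pytest.raises(KeyError):
            model.forward({"raw": np.zeros((1, 12, 5000), dtype=np.float32)})

    def test_empty_module_list_rejected(self):
        with pytest.raises(ValueError):
            ModuleConfig(enabled=())

    def test_softmax_scores_sum_to_one(self):
        model = FusionModel(ModuleConfig(enabled=("raw_entropy",), n_classes=5))
        probs = model.predict_proba(
            {"raw_entropy": RNG.standard_normal((4, 156)).astype(np.float32)})
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, rtol=1e-12)

    def test_checkpoint_round_trip(self, tmp_path):
        cfg = ModuleConfig(enabled=("raw_entropy",), n_classes=3, seed=9)
        model = FusionModel(cfg)
        x = {"raw_entropy": RNG.standard_normal((4, 156)).astype(np.float32)}
        ref = model.forward(x)
        path = str(tmp_path / "ckpt.npz")
        model.save(path)
        back = FusionModel.load(path, cfg)
        np.testing.assert_array_equal(back.forward(x), ref)


class TestGradients:
    def test_entropy_path_matches_finite_differences(self):
        cfg = ModuleConfig(enabled=("raw_entropy",), n_classes=3, seed=1,
                           dtype=np.float64)
        model = FusionModel(cfg)
        rng = np.random.default_rng(0)
        batch = {"raw_entropy": rng.standard_normal((4, 156))}
        labels = rng.integers(0, 3, 4)
        _, d = softmax_cross_entropy(model.forward(batch), labels)
        for p in model.parameters():
            p.grad[...] = 0
        model.backward(d)
        for p in model.parameters():
            flat, gflat = p.data.ravel(), p.grad.ravel()
            for idx in rng.choice(flat.size, size=3, replace=False):
                eps, old = 1e-6, flat[idx]
                flat[idx] = old + eps
                lp, _ = softmax_cross_entropy(model.forward(batch), labels)
                flat[idx] = old - eps
                lm, _ = softmax_cross_entropy(model.forward(batch), labels)
                flat[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gflat[idx], rel=1e-4, abs=1e-8)
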