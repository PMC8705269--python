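import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecgfusion.entropy import (
    EntropyConfig,
    approximate_entropy,
    extropy,
    feature_names,
    feature_vector,
    lead_features,
    permutation_entropy,
    renyi_entropy,
    sample_entropy,
    shannon_entropy,
    spectral_entropy,
    svd_entropy,
    tsallis_entropy,
)


def sample_entropy_bruteforce(x, m=2, r_factor=0.2):
    """Independent O(n^2) double-loop template-matching oracle."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    r = r_factor * np.std(x)

    def matches(k):
        total = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + t] - x[j + t]) for t in range(k)) <= r:
                    total += 1
        return total

    b, a = matches(m), matches(m + 1)
    return -math.log2(a / b) if a and b else 0.0


class TestClosedForms:
    def test_constant_signal_all_zero(self):
        x = np.full(120, 2.7)
        assert shannon_entropy(x) == 0
        assert approximate_entropy(x) == 0
        assert sample_entropy(x) == 0
        assert permutation_entropy(x) == 0
        assert spectral_entropy(x) == 0
        assert svd_entropy(x) == 0
        assert renyi_entropy(x) == 0
        assert tsallis_entropy(x) == 0
        assert extropy(x) == 0

    def test_two_equal_bins(self):
        x = np.tile([0.0, 1.0], 50)
        assert shannon_entropy(x, bins=2) == 1.0
        assert renyi_entropy(x, bins=2, alpha=2) == 1.0
        assert tsallis_entropy(x, bins=2, q=2) == 0.5
        assert extropy(x, bins=2) == 1.0

    def test_four_equal_bins(self):
        assert shannon_entropy(np.tile([0, 1, 2, 3.0], 25), bins=4) == 2.0

    def test_monotone_ramp_permutation_zero(self):
        assert permutation_entropy(np.arange(100.0)) == 0

    def test_balanced_patterns_reach_one(self):
        """A sequence whose six overlapping order-3 windows realize all six
        ordinal patterns exactly once has maximal (= 1.0) entropy."""
        x = np.array([0, 1, 5, 4, 3, 7, 2, 6], dtype=float)
        windows = {tuple(np.argsort(x[i : i + 3])) for i in range(6)}
        assert len(windows) == 6  # construction is pattern-complete
        assert permutation_entropy(x) == pytest.approx(1.0, abs=1e-12)

    def test_renyi_limits_to_shannon(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        h = shannon_entropy(x)
        assert abs(renyi_entropy(x, alpha=1.001) - h) < 0.01
        assert abs(renyi_entropy(x, alpha=0.999) - h) < 0.01

    def test_alpha_q_one_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            renyi_entropy(x, alpha=1)
        with pytest.raises(ValueError):
            tsallis_entropy(x, q=1)


class TestTemplateEntropies:
    @pytest.mark.parametrize("n", [20, 30, 50])
    def test_sample_entropy_matches_bruteforce(self, n):
        rng = np.random.default_rng(n)
        x = rng.standard_normal(n)
        assert abs(sample_entropy(x) - sample_entropy_bruteforce(x)) < 1e-10

    def test_periodic_lower_than_noise(self):
        rng = np.random.default_rng(3)
        square = np.tile([1.0] * 5 + [-1.0] * 5, 20)
        noise = rng.standard_normal(200)
        noise = noise / noise.std() * square.std()
        assert sample_entropy(square) < sample_entropy(noise)
        assert approximate_entropy(square) < approximate_entropy(noise)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.arange(3.0), m=2)


class TestSpectralAndSvd:
    def test_pure_tone_near_zero(self):
        t = np.arange(1024)
        x = np.sin(2 * np.pi * 32 * t / 1024)
        assert spectral_entropy(x) < 0.05

    def test_white_noise_near_one(self):
        x = np.random.default_rng(7).standard_normal(4096)
        assert spectral_entropy(x) > 0.9

    def test_scale_invariant(self):
        x = np.random.default_rng(1).standard_normal(512)
        assert spectral_entropy(3.7 * x) == pytest.approx(spectral_entropy(x), abs=1e-12)

    def test_svd_positive_for_noise(self):
        x = np.random.default_rng(2).standard_normal(300)
        assert svd_entropy(x) > 0


class TestInvariances:
    @given(st.floats(min_value=-10, max_value=10),
           st.floats(min_value=0.1, max_value=10))
    def test_offset_and_positive_scale(self, offset, scale):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(150)
        y = scale * x + offset
        cfg = EntropyConfig()
        np.testing.assert_allclose(
            lead_features(y, cfg), lead_features(x, cfg), rtol=1e-7, atol=1e-9)

    @given(st.sampled_from(["exp", "cube", "arctan"]))
    def test_permutation_entropy_monotone_invariant(self, fname):
        f = {"exp": np.exp, "cube": lambda v: v**3, "arctan": np.arctan}[fname]
        x = np.random.default_rng(5).standard_normal(200)
        assert permutation_entropy(f(x)) == permutation_entropy(x)


class TestFeatureVector:
    def test_length_156_for_12_leads(self):
        x = np.random.default_rng(0).standard_normal((12, 100))
        assert feature_vector(x).shape == (156,)

    def test_length_13_for_single_lead(self):
        x = np.random.default_rng(0).standard_normal((1, 100))
        assert feature_vector(x).shape == (13,)

    def test_zero_record_all_zero(self):
        assert np.all(feature_vector(np.zeros((12, 100))) == 0)

    def test_lead_permutation_permutes_blocks(self):
        x = np.random.default_rng(1).standard_normal((12, 100))
        v = feature_vector(x)
        perm = np.random.default_rng(2).permutation(12)
        vp = feature_vector(x[perm])
        for new_pos, old_lead in enumerate(perm):
            np.testing.assert_array_equal(
                vp[13 * new_pos : 13 * (new_pos + 1)],
                v[13 * old_lead : 13 * (old_lead + 1)])

    def test_non_finite_rejected(self):
        x = np.zeros((12, 100))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            feature_vector(x)

    def test_names_align(self):
        names = feature_names()
        assert len(names) == 156
        assert names[0] == "lead0_shannon"
        assert names[13] == "lead1_shannon"
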