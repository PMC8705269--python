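"""Consensus R-peak detection on a synthetic 12-lead record.

Generates one clean 75-BPM record with known R-peak positions, runs all six
per-lead detectors on all 12 leads (72 candidate lists), takes the median of
the 72 counts as the beat count, and localizes the peaks with 1-D k-means.
"""

import numpy as np

from ecgfusion import SyntheticSpec, generate_synthetic_record
from ecgfusion.consensus import compute_consensus
from ecgfusion.detectors import DetectorBank

record, true_peaks = generate_synthetic_record(
    SyntheticSpec(bpm_mean=75, noise_sd=0.1, rng_seed=42))
result = compute_consensus(record, DetectorBank.default())

print(f"true beats:       {len(true_peaks)}")
print(f"consensus count:  {result.n_R}  (median of 72 detector-lead counts)")
print(f"estimated BPM:    {result.bpm:.0f}")
errors = [int(np.abs(true_peaks - p).min()) for p in result.positions]
print(f"localization err: {errors} samples (50 ms = 25 samples at 500 Hz)")
# The count should match the truth exactly and every localized peak should
# sit within a few samples of a true R peak despite the added noise.
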