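# ecgfusion

Multi-detector R-peak consensus, QRS segmentation, entropy features and
modular neural classification of 12-lead ECG records.

## What it does and who it is for

Clinical ECGs are recorded for a fixed time (10 s at 500 Hz here), not a
fixed number of heartbeats. `ecgfusion` is a library for researchers working
on beat-level ECG classification under that constraint. It provides:

1. **Consensus R-peak detection.** Six classical single-lead detectors
   (Pan–Tompkins, Elgendi two-average, stationary-wavelet, and simplified
   Hamilton-, Christov- and Engzee-style variants) run on every one of the
   12 leads, yielding 72 candidate lists per record. The beat count `n_R` is
   the **median of the 72 counts**; peak positions come from **1-D k-means**
   (deterministic quantile-initialized Lloyd iteration) on the pooled
   candidate indices with k = `n_R`. Fusing many weak, disagreeing detectors
   across leads is far more robust than any single detector on any single
   lead.
2. **Beat segmentation.** Records are cut halfway between consecutive
   consensus peaks, the edge segments are dropped (n_R − 2 kept, each
   holding exactly one centered R peak), and every beat is linearly
   resampled to 12 × 100.
3. **Entropy feature bank.** 13 information-theoretic features per lead
   (Shannon, approximate, sample, permutation, spectral, SVD, Rényi,
   Tsallis, extropy and four parameterized variants) — 156 features for a
   12-lead input, computed for the raw signal and for each beat.
4. **Modular classifier.** Four encoder modules — a convolutional raw-signal
   encoder, two shallow entropy encoders, and a permutation-invariant set
   encoder g: R¹²ˣ¹⁰⁰ → R²⁴ with adaptive max/average pooling over the
   variable-length beat set — each emit a 20-dim code; any of the 15
   non-empty subsets fuses through a fully-connected head (width 20 × the
   number of enabled modules). Training follows a fixed protocol: Adam from
   lr 0.001 halved after 50 stagnant training epochs (floor 1e-6), early
   stopping after 250 stagnant validation epochs, epochs of 10 batches built
   from QRS-count-homogeneous chunks (≤256 records each), 70/15/15 splits
   repeated over five seeds.

The neural stack (1-D convolutions with im2col, pooling, manual
backpropagation, Adam) is implemented in numpy inside the package, so the
classifier runs anywhere scientific Python runs. Data I/O supports
WFDB format-16 signal files with PTB-XL-style metadata CSVs (label-certainty
and subclass-population filtering included), and a synthetic 12-lead
generator with exact ground-truth R-peaks makes every stage testable without
any download.

## Worked example

```python
import numpy as np
from ecgfusion import SyntheticSpec, generate_synthetic_record
from ecgfusion.consensus import compute_consensus
from ecgfusion.detectors import DetectorBank

record, true_peaks = generate_synthetic_record(
    SyntheticSpec(bpm_mean=75, noise_sd=0.1, rng_seed=42))
result = compute_consensus(record, DetectorBank.default())
print(len(true_peaks), result.n_R, result.bpm)
print([int(np.abs(true_peaks - p).min()) for p in result.positions])
```

prints

```
12 12 72.0
[0, 0, 0, 0, 3, 0, 0, 0, 0, 0, 0, 0]
```

— the consensus recovers all 12 beats of the 72-BPM record exactly, and
every localized peak lies within 3 samples (6 ms) of a true R peak despite
0.1 mV added noise. `examples/` contains this script plus three more:
segmentation + entropy features, the architecture arithmetic (the kernel-1
reduction that shrinks the raw encoder's final layer from 38,400 weights to
800 + 192), and end-to-end training with cross-validated metrics.

A thin CLI wraps the same functions for shell use:

```bash
ecgfusion simulate --out data --n 200 --classes 2 --seed 0
ecgfusion detect --data data --out detections.csv
ecgfusion run-all --out results --n 200 --epochs 40
```

## Layout

```
src/ecgfusion/
  data_io.py       records, metadata filtering, synthetic ECG, WFDB I/O
  detectors.py     the six per-lead R-peak detectors + pluggable bank
  consensus.py     median beat count, 1-D k-means localization
  segmentation.py  midpoint cutting, edge removal, resampling to 12x100
  entropy.py       the 13-feature per-lead entropy bank
  nn.py            numpy layer framework (conv/pool/linear/Adam)
  model.py         encoder modules, fusion head, architecture arithmetic
  training.py      splits, chunked batches, schedulers, train loop
  evaluation.py    metrics, macro AUC, cross-validation aggregation
  pipeline.py      end-to-end feature extraction and experiments
  cli.py           thin argparse CLI over the library
```

`docs/methods.md` describes the algorithms, parameter choices, synthetic
data assumptions and known limitations in detail.
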