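# Methods

## Problem

Clinical 12-lead ECGs are recorded for a fixed duration (10 s at 500 Hz
here), not a fixed number of heartbeats, so beat-level analysis must first
find the R peaks, and any beat-level classifier must cope with a
variable-length collection of beats per record.  This package implements a
complete pipeline for that setting: a multi-detector, multi-lead R-peak
consensus; midpoint segmentation of records into single-beat QRS windows; a
per-lead entropy feature bank; and a modular neural classifier whose
combination of encoder modules can be varied.

## R-peak consensus

Six classical single-lead detectors (Pan–Tompkins, Elgendi two-average,
stationary-wavelet, and simplified Hamilton-, Christov- and Engzee-style
variants) each run on each of the 12 leads, producing 72 candidate index
lists per record. Two aggregation steps follow:

1. **Count.** The beat count `n_R` is the median of the 72 per-entry
   cardinalities. For an even number of entries the mean of the two middle
   order statistics is rounded half up, since k-means needs an integer k.
   Entries from a detector that fails on a lead stay in the median with
   cardinality 0; robustness to individual failures is the point of pooling
   72 sources.
2. **Location.** All candidate indices are pooled into one 1-D point set and
   clustered by Lloyd's k-means with k = `n_R`. Centers are initialized at
   the (2i+1)/(2k) quantiles of the pooled points, iterated until
   assignments stabilize (≤300 iterations); an emptied cluster is re-seeded
   at the point farthest from its nearest center. This makes localization
   fully deterministic without a random seed. Rounded centers, sorted
   ascending, are the consensus R-peak positions; BPM = `n_R` × 60 /
   duration.

The detector implementations are noise-hardened in one shared way: the
adaptive dual-threshold peak picker (running signal- and noise-peak
estimates, THR = NPK + f·(SPK−NPK)) keeps its threshold above a static floor
tied to the candidate-height distribution (a fraction of the 75th percentile
and of the maximum). Without the floor, a run of accepted noise peaks drags
the running signal estimate down and the detector cascades into
over-detection on low-amplitude leads. The two-average detector analogously
rejects blocks whose peak height falls below 20% of the tallest block.
The Hamilton-, Christov- and Engzee-style detectors are simplified variants
(different pre-filter envelopes feeding this common core), not bit-exact
re-implementations of the published algorithms; the bank accepts any
external `f(lead, fs) -> indices` callable where exact versions are wanted.

## Segmentation

With consensus positions p₁ < … < pₙ, cut points are floor((pⱼ+pⱼ₊₁)/2);
intervals are half-open, so the n intervals exactly tile the record.  The
first and last intervals (which contain the recording edges rather than a
centered beat) are discarded, leaving n−2 segments with exactly one R peak
each; records with n < 3 are flagged unusable and dropped from training
(counted in logs). Each segment is linearly interpolated per lead onto 100
equally spaced points (endpoints preserved). Linear interpolation was chosen
over Fourier/polyphase resampling for determinism and endpoint preservation.
The original-length/100 ratio and the record BPM are retained as metadata
but are not fed to any encoder.

## Entropy bank

Thirteen features per lead, computed identically for 5000-sample raw leads
and 100-sample segments; all logarithms base 2:

| feature | parameters (default) |
| --- | --- |
| Shannon entropy | 10 equal-width histogram bins |
| approximate entropy | m = 2, r = 0.2·SD, Chebyshev |
| sample entropy | m = 2, r = 0.2·SD, self-matches excluded |
| permutation entropy | order 3, delay 1, normalized by log2(3!) |
| spectral entropy | periodogram, DC bin dropped, normalized |
| SVD entropy | embedding order 3, delay 1, mean-centered |
| Rényi entropy | α = 2, same histogram |
| Tsallis entropy | q = 2, same histogram |
| extropy | same histogram |
| Rényi (α = 0.5), Tsallis (q = 0.5), permutation (order 4), approximate (m = 3) | variants |

The canonical bank of this pipeline has nine named measures but a
156-dimensional per-record contract (12 leads × 13); the four parameterized
variants complete the count transparently and are configurable
(`EntropyConfig.feature_list`). Degenerate zero-variance inputs return 0 for
every feature so a flat lead cannot inject NaNs into training. Two
conventions were chosen to make the whole bank invariant under positive
affine transforms of the signal: the spectral entropy excludes the
zero-frequency bin, and the SVD entropy operates on the mean-centered
signal. Approximate/sample entropy use cKDTree Chebyshev neighbor counting;
an O(n²) brute-force oracle validates sample entropy to 1e−10 in the tests.

## Classifier

Four encoder modules, each emitting 20 dimensions, are composable into all
15 non-empty subsets:

* **raw**: Conv(12→24,k3,p1)/MaxPool(k3,s3) ×5 with channel progression
  24-48-64-72-96 (lengths 5000→1666→555→185→61→20, floor division), a
  kernel-1 Conv 96→2 reducing the flatten from 1920 to 40 dims (800-weight
  final FC instead of 38,400, at the cost of 192 reduction weights), FC
  40→20.
* **raw entropy**: FC 156→20, leaky ReLU, FC 20→20.
* **QRS set**: a shared beat encoder g: R^{12×100}→R^{24} (three
  Conv(k3,p1)/MaxPool(k2) stages, kernel-1 Conv to 2 channels, flatten) maps
  over the variable-length beat set; elementwise (adaptive) max and average
  pooling over the set give a 48-dim summary; FC 48→20. The printed form of
  the beat-encoder table (zero padding on the middle convolutions) flattens
  to 22, contradicting the 24-dim contract used downstream (48 = 2×24);
  padding 1 everywhere honors the contract and is the default
  (`qrs_padding_as_printed=True` selects the 22-dim variant).
* **QRS entropy set**: max/avg pooling of the per-beat 156-dim entropy
  vectors (312 concatenated), FC 312→20, leaky ReLU, FC 20→20.

Leaky ReLU (slope 0.01) follows every convolution. The fusion head
concatenates the enabled modules' outputs, applies leaky ReLU and a final FC
to the class count; raw scores are emitted, with softmax applied inside the
cross-entropy loss. Weight counts quoted above exclude biases. Weights are
Kaiming-uniform (fan-in, leaky-ReLU gain), seeded per run. No input
normalization is applied by default; a per-lead z-score switch exists.

The network stack is a small purpose-built numpy layer framework (im2col
convolutions, non-overlapping max pooling, manual backpropagation, Adam);
finite-difference tests validate every gradient path (apparent residuals in
whole-model checks trace to max-pool argmax flips, i.e. genuine kinks).
Training tensors are float32; float64 is used in gradient tests.

## Training protocol

70/15/15 train/validation/test split by seeded shuffle, repeated with five
seeds (non-exhaustive cross-validation). Batches must be rectangular, so
records are chunked by QRS-segment count; each batch samples a chunk from
the empirical chunk distribution and takes the whole chunk if ≤256 records,
else 256 without replacement. An epoch is 10 batches. Adam starts at lr
0.001; the rate halves after 50 epochs without a new best *training*
accuracy (counter reset by improvements and reductions, floor 1e−6);
training stops after 250 epochs without a new best *validation* accuracy or
at 10,000 epochs, and the best-validation weights are retained. The
monitored quantity is accuracy for both schedulers (loss monitoring is a
config option); the loss is cross-entropy. Optional restarts
(`train_with_restarts`) re-train fresh networks after early stopping and
keep the best-validation model; the default is no restarts.

## Evaluation

One-vs-rest confusion counts per class give accuracy, precision, recall and
F1 (zero denominators resolve to 0); multi-class values are unweighted macro
averages, and AUC is macro one-vs-rest on softmax scores (binary: threshold
sweep on the positive-class score). Across the five splits, metrics are
summarized as min–max range, mean and *population* standard deviation
(ddof = 0; with n = 5 the sample-sd alternative is about 12% larger),
rendered as "max–min | mean | std" rows sorted by descending maximum
accuracy.

## Synthetic data

The generator emulates the study conditions so the whole pipeline is
testable without any download: 12-lead, 10 s, 500 Hz records built from
per-beat P-QRS-T Gaussian-bump templates placed at the beat rate (a clean
record carries round(BPM/6) beats; `bpm_jitter` perturbs the inter-beat
intervals), projected through a per-lead amplitude vector (including an
inverted aVR-like lead spanning 0.35–1.0 mV R amplitudes), plus white
Gaussian noise, quantized to 1/1000 mV (16-bit ADC at gain 1000, which makes
WFDB round-trips bit-exact). `qrs_width_ms` is the Q-to-S duration, default
80 ms (physiological); synthetic diagnostic classes differ in QRS width
(+25 ms per class, emulating conduction-delay widening), T amplitude and
heart-rate range, making small cohorts learnably separable.

What the generator does **not** emulate: beat-to-beat morphology variation,
arrhythmic rhythms (irregular RR beyond Gaussian jitter), baseline wander,
power-line interference, electrode artifacts, or pathological ST/T
morphologies. Passing tests on this data therefore demonstrates the
correctness of the pipeline's mechanics (counting, localization,
segmentation, feature computation, optimization) and its robustness to
white noise up to 20% of the nominal R amplitude — not clinical-grade
classification performance. Full-scale results require the public PTB-XL
dataset and long training (see `scripts/ptbxl_full_run.py`); the package's
own tests use desk-scale cohorts (100 records for detector recovery, 200
records/40 epochs for the end-to-end training check, 120 records/25
epochs/5 splits in the acceptance script), sizes chosen to exercise every
protocol component at laptop cost.

## Numerical choices and edge cases

* Sample indices are 0-based; every interval is half-open [start, end).
* Even-length median rounds half up; an all-empty detection set or a pooled
  candidate set smaller than k raises a degenerate-record error.
* k-means rounding collisions (near-coincident centers) are resolved by
  bumping to the next integer to keep positions strictly increasing.
* Histogram features use equal-width bins over [min, max]; constant signals
  land in one bin and yield 0.
* Sample entropy returns 0 when no template pairs match at either length.
* Empty beat sets are rejected by the set encoders; records that would
  produce them are dropped at segmentation time and counted.

## Known limitations

* The three "-style" detectors approximate their namesakes; studies needing
  the published algorithms should register exact implementations.
* The entropy bank's four variant features are this package's choice; a
  different completion of the 13-feature contract would change the
  raw-entropy and QRS-entropy modules' inputs.
* Training runs single-threaded on CPU via numpy; full-scale PTB-XL
  training is possible but slow (hours), and no GPU path is provided.
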