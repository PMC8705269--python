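"""Per-lead R-peak detectors.

Each detector maps one 5000-sample lead to a sorted array of candidate R-peak
sample indices.  Six slots are provided, mirroring the classical single-lead
detector families commonly combined on 12-lead data:

* ``pan_tompkins`` — band-pass, differentiate, square, moving-window
  integration, adaptive dual thresholds with search-back;
* ``two_average`` — Elgendi-style two moving averages (QRS- and beat-scale)
  generating blocks of interest;
* ``swt`` — stationary-wavelet-transform detail band, squared, with adaptive
  thresholding;
* ``hamilton`` / ``christov`` / ``engzee`` — simplified variants in the
  spirit of the respective published detectors (different pre-filter
  envelopes feeding a common adaptive peak-picking core), not bit-exact
  re-implementations.

The bank is pluggable: any callable ``f(lead_signal, fs) -> indices`` can be
registered, so bit-exact third-party implementations can be dropped in.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Iterable, Mapping

import numpy as np
from scipy import signal as sps

Detector = Callable[[np.ndarray, int], np.ndarray]


def _bandpass(x: np.ndarray, fs: int, lo: float, hi: float, order: int = 2) -> np.ndarray:
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, int(width))
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def _snap_to_peak(x: np.ndarray, idx: np.ndarray, fs: int, window_s: float = 0.05) -> np.ndarray:
    """Refine envelope candidates to the local extremum of the raw lead.

    The R deflection may point up or down depending on the lead axis, so the
    extremum of |x - median(x)| inside a +-window_s neighbourhood is used.
    """
    if len(idx) == 0:
        return np.array([], dtype=int)
    dev = np.abs(x - np.median(x))
    w = int(window_s * fs)
    out = []
    for i in idx:
        lo, hi = max(0, i - w), min(len(x), i + w + 1)
        out.append(lo + int(np.argmax(dev[lo:hi])))
    return np.array(sorted(set(out)), dtype=int)


def _enforce_refractory(idx: np.ndarray, amp: np.ndarray, fs: int, refractory_s: float = 0.2) -> np.ndarray:
    """Drop candidates closer than the refractory period, keeping the larger."""
    if len(idx) == 0:
        return idx
    keep: list[int] = []
    gap = refractory_s * fs
    for i in idx:
        if keep and i - keep[-1] < gap:
            if amp[i] > amp[keep[-1]]:
                keep[-1] = int(i)
        else:
            keep.append(int(i))
    return np.array(keep, dtype=int)


def _adaptive_pick(env: np.ndarray, fs: int, frac: float = 0.25,
                   refractory_s: float = 0.25, search_back: bool = False,
                   floor_frac: float = 0.3,
                   floor_max_frac: float = 0.25) -> np.ndarray:
    """Adaptive dual-threshold peak picking on a non-negative envelope.

    Running signal-peak (SPK) and noise-peak (NPK) levels set the detection
    threshold THR = NPK + frac * (SPK - NPK), kept above a static floor of
    ``floor_frac`` times the 75th percentile of candidate heights so that a
    run of accepted noise peaks cannot collapse the threshold; with
    ``search_back``, an overlong R-R gap triggers a second pass at THR/2
    inside the gap.
    """
    if env.max() <= 0:
        return np.array([], dtype=int)
    cand, _ = sps.find_peaks(env, distance=max(1, int(refractory_s * fs)))
    if len(cand) == 0:
        return np.array([], dtype=int)
    floor = max(floor_frac * float(np.percentile(env[cand], 75)),
                floor_max_frac * float(env[cand].max()))
    head = env[: int(2 * fs)]
    spk = float(head.max()) * 0.5 if head.size else float(env.max()) * 0.5
    npk = float(np.mean(head)) * 0.5 if head.size else 0.0
    accepted: list[int] = []
    for i in cand:
        thr = max(npk + frac * (spk - npk), floor)
        if env[i] > thr:
            accepted.append(int(i))
            spk = 0.125 * env[i] + 0.875 * spk
        else:
            npk = 0.125 * env[i] + 0.875 * npk
    if search_back and len(accepted) >= 2:
        rr = np.diff(accepted)
        mean_rr = float(np.mean(rr))
        extra: list[int] = []
        thr_half = max(npk + frac * (spk - npk), floor) / 2.0
        for a, b, gap in zip(accepted[:-1], accepted[1:], rr):
            if gap > 1.66 * mean_rr:
                inside = cand[(cand > a + int(refractory_s * fs)) & (cand < b - int(refractory_s * fs))]
                inside = [int(j) for j in inside if env[j] > thr_half]
                if inside:
                    extra.append(int(max(inside, key=lambda j: env[j])))
        accepted = sorted(accepted + extra)
    return np.array(accepted, dtype=int)


def pan_tompkins_detect(x: np.ndarray, fs: int = 500) -> np.ndarray:
    """Pan–Tompkins: band-pass 5–15 Hz, derivative, square, 150 ms moving
    window integration, adaptive thresholds with search-back."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return np.array([], dtype=int)
    bp = _bandpass(x, fs, 5.0, 15.0, order=2)
    deriv = np.gradient(bp)
    mwi = _moving_average(deriv**2, 0.15 * fs)
    cand = _adaptive_pick(mwi, fs, frac=0.25, refractory_s=0.2, search_back=True)
    snapped = _snap_to_peak(x, cand, fs)
    return _enforce_refractory(snapped, np.abs(x - np.median(x)), fs)


def two_average_detect(x: np.ndarray, fs: int = 500) -> np.ndarray:
    """Two-average (Elgendi-style): band-pass 8–20 Hz, square, QRS-scale vs
    beat-scale moving averages define blocks of interest whose maxima are
    the peaks."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return np.array([], dtype=int)
    bp = _bandpass(x, fs, 8.0, 20.0, order=3)
    y = bp**2
    ma_peak = _moving_average(y, 0.12 * fs)
    ma_beat = _moving_average(y, 0.60 * fs)
    thr = ma_beat + 0.15 * float(np.mean(y))
    blocks = ma_peak > thr
    idx = []
    in_block = False
    start = 0
    min_width = int(0.06 * fs)
    for i, b in enumerate(blocks):
        if b and not in_block:
            in_block, start = True, i
        elif not b and in_block:
            in_block = False
            if i - start >= min_width:
                idx.append(start + int(np.argmax(y[start:i])))
    if in_block and len(blocks) - start >= min_width:
        idx.append(start + int(np.argmax(y[start:])))
    idx_arr = np.array(idx, dtype=int)
    if len(idx_arr):
        # reject blocks far below the tallest one (squared scale)
        heights = y[idx_arr]
        idx_arr = idx_arr[heights > 0.2 * heights.max()]
    snapped = _snap_to_peak(x, idx_arr, fs)
    return _enforce_refractory(snapped, np.abs(x - np.median(x)), fs, 0.25)


def swt_detect(x: np.ndarray, fs: int = 500) -> np.ndarray:
    """Stationary wavelet transform detector: the db3 detail band covering
    roughly 8–16 Hz is squared and fed to adaptive thresholding."""
    import pywt

    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return np.array([], dtype=int)
    level = max(1, int(np.log2(fs / 16.0)))  # band ~ fs/2^(level+1) .. fs/2^level
    pad = (-len(x)) % (2**level)
    xp = np.pad(x, (0, pad), mode="edge")
    coeffs = pywt.swt(xp, "db3", level=level, trim_approx=False)
    detail = coeffs[0][1][: len(x)]  # coarsest detail band of the decomposition
    env = _moving_average(detail**2, 0.1 * fs)
    cand = _adaptive_pick(env, fs, frac=0.3, refractory_s=0.25)
    snapped = _snap_to_peak(x, cand, fs)
    return _enforce_refractory(snapped, np.abs(x - np.median(x)), fs)


def hamilton_detect(x: np.ndarray, fs: int = 500) -> np.ndarray:
    """Hamilton-style (simplified): band-pass 8–16 Hz, rectify, 80 ms moving
    average, adaptive threshold from the recent peak history."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return np.array([], dtype=int)
    bp = _bandpass(x, fs, 8.0, 16.0, order=1)
    env = _moving_average(np.abs(bp), 0.08 * fs)
    cand, _ = sps.find_peaks(env, distance=int(0.2 * fs))
    if len(cand) == 0:
        return np.array([], dtype=int)
    history: list[float] = []
    accepted = []
    floor = max(0.35 * float(np.percentile(env[cand], 75)),
                0.4 * float(env[cand].max()))
    thr = max(0.45 * float(np.percentile(env[cand], 75)), floor)
    for i in cand:
        if env[i] > thr:
            accepted.append(int(i))
            history.append(float(env[i]))
            thr = max(0.45 * float(np.mean(history[-8:])), floor)
    snapped = _snap_to_peak(x, np.array(accepted, dtype=int), fs)
    return _enforce_refractory(snapped, np.abs(x - np.median(x)), fs)


def christov_detect(x: np.ndarray, fs: int = 500) -> np.ndarray:
    """Christov-style (simplified): cascaded short moving averages suppress
    power-line and EMG bands, then a smoothed absolute-derivative complex
    lead is thresholded adaptively with a steep post-beat decay emulated by
    the refractory rule."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return np.array([], dtype=int)
    y = _moving_average(_moving_average(x, fs // 50), fs * 28 // 1000)
    env = _moving_average(np.abs(np.gradient(y)), 0.04 * fs)
    cand = _adaptive_pick(env, fs, frac=0.35, refractory_s=0.25, floor_max_frac=0.4)
    snapped = _snap_to_peak(x, cand, fs)
    return _enforce_refractory(snapped, np.abs(x - np.median(x)), fs, 0.25)


def engzee_detect(x: np.ndarray, fs: int = 500) -> np.ndarray:
    """Engzee-style (simplified): lag-4 difference emphasises the steep QRS
    slopes; its squared, 30 ms-smoothed envelope is thresholded adaptively."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return np.array([], dtype=int)
    bp = _bandpass(x, fs, 1.0, 30.0, order=2)
    diff = np.zeros_like(bp)
    diff[4:] = bp[4:] - bp[:-4]
    env = _moving_average(diff**2, 0.05 * fs)
    cand = _adaptive_pick(env, fs, frac=0.35, refractory_s=0.25)
    snapped = _snap_to_peak(x, cand, fs)
    return _enforce_refractory(snapped, np.abs(x - np.median(x)), fs)


NATIVE_DETECTORS: dict[str, Detector] = {
    "hamilton": hamilton_detect,
    "two_average": two_average_detect,
    "swt": swt_detect,
    "christov": christov_detect,
    "pan_tompkins": pan_tompkins_detect,
    "engzee": engzee_detect,
}


@dataclasses.dataclass
class DetectorBank:
    """Ordered, named collection of per-lead detectors."""

    detectors: dict[str, Detector]

    def __post_init__(self) -> None:
        if not self.detectors:
            raise ValueError("detector bank must contain at least one detector")

    @classmethod
    def default(cls) -> "DetectorBank":
        """The full six-detector bank (72 entries on a 12-lead record)."""
        return cls(dict(NATIVE_DETECTORS))

    @classmethod
    def subset(cls, names: Iterable[str]) -> "DetectorBank":
        unknown = [n for n in names if n not in NATIVE_DETECTORS]
        if unknown:
            raise KeyError(f"unknown detectors: {unknown}")
        return cls({n: NATIVE_DETECTORS[n] for n in names})

    def register(self, name: str, func: Detector) -> None:
        self.detectors[name] = func

    @property
    def names(self) -> list[str]:
        return list(self.detectors)

    def __len__(self) -> int:
        return len(self.detectors)

    def items(self) -> Mapping[str, Detector]:
        return self.detectors
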