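"""Per-lead entropy feature bank.

Thirteen information-theoretic features are computed per lead, for both the
raw 5000-sample signal and each 100-sample QRS segment, giving 156 features
on 12-lead input.  Nine are the classical measures (Shannon, approximate,
sample, permutation, spectral, SVD, Renyi, Tsallis entropy and extropy); the
remaining four are parameterized variants (Renyi alpha=0.5, Tsallis q=0.5,
permutation order=4, approximate entropy m=3) chosen to complete the
13-feature contract — a non-canonical but transparent, configurable choice.

Conventions: logarithms are base 2 throughout; template tolerances r are
multiples of the per-lead standard deviation (Chebyshev distance);
zero-variance inputs yield 0 for every feature so that flat leads cannot
poison training.  All features are invariant under additive offsets, and the
histogram-, ordinal- and spectrum-based ones under positive rescaling too.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from scipy.spatial import cKDTree


def _hist_probs(x: np.ndarray, bins: int) -> np.ndarray:
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / x.size
    return p


def shannon_entropy(x: np.ndarray, bins: int = 10) -> float:
    """Histogram Shannon entropy in bits over equal-width bins."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    p = _hist_probs(x, bins)
    return float(-np.sum(p * np.log2(p)))


def _embed(x: np.ndarray, order: int, delay: int = 1) -> np.ndarray:
    """Delay embedding: rows are (x[i], x[i+delay], ..., x[i+(order-1)delay])."""
    n = len(x) - (order - 1) * delay
    if n < 1:
        raise ValueError("signal too short for this embedding")
    return sliding_window_view(x, (order - 1) * delay + 1)[:, ::delay]


def approximate_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Approximate entropy: phi(m) - phi(m+1), Chebyshev tolerance r = r_factor * SD.

    phi(k) is the mean base-2 log of the fraction of templates (self-matches
    included) within r of each length-k template.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= m + 1:
        raise ValueError("signal too short")
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def phi(k: int) -> float:
        emb = _embed(x, k)
        counts = cKDTree(emb).query_ball_point(emb, r, p=np.inf, return_length=True)
        return float(np.mean(np.log2(counts / emb.shape[0])))

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy: -log2(A/B) with self-matches excluded.

    B counts template pairs matching at length m, A at length m + 1, both over
    the same n - m template start indices.  Degenerate cases (zero variance,
    or no matches at either length) return 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) <= m + 1:
        raise ValueError("signal too short")
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    r = r_factor * sd

    def pairs(k: int) -> int:
        emb = _embed(x, k)[: len(x) - m]  # same template count for both lengths
        tree = cKDTree(emb)
        total = tree.count_neighbors(tree, r, p=np.inf)  # ordered pairs incl. self
        return int((total - emb.shape[0]) // 2)

    b = pairs(m)
    a = pairs(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return float(-math.log2(a / b))


def permutation_entropy(
    x: np.ndarray, order: int = 3, delay: int = 1, normalize: bool = True
) -> float:
    """Shannon entropy of the ordinal-pattern distribution, / log2(order!)."""
    x = np.asarray(x, dtype=float)
    emb = _embed(x, order, delay)
    patterns = np.argsort(emb, axis=1, kind="stable")
    codes = (patterns * (order ** np.arange(order))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log2(p)))
    if normalize:
        h /= math.log2(math.factorial(order))
    return h


def spectral_entropy(x: np.ndarray, fs: float = 1.0, normalize: bool = True) -> float:
    """Shannon entropy of the normalized periodogram, / log2(#bins).

    The zero-frequency bin is excluded so the feature depends on the signal's
    variation, not its offset.
    """
    x = np.asarray(x, dtype=float)
    _, psd = sps.periodogram(x, fs=fs)
    psd = psd[1:]
    total = psd.sum()
    if total <= 0:
        return 0.0
    p = psd[psd > 0] / total
    h = float(-np.sum(p * np.log2(p)))
    if normalize:
        h /= math.log2(len(psd))
    return h


def svd_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Shannon entropy of the normalized singular values of the embedding.

    The signal is mean-centered first so the feature reflects the signal's
    dynamics rather than its DC offset (keeping it offset-invariant like the
    rest of the bank).
    """
    x = np.asarray(x, dtype=float)
    emb = _embed(x - x.mean(), order, delay)
    s = np.linalg.svd(emb, compute_uv=False)
    s = s[s > s.max() * max(emb.shape) * np.finfo(float).eps] if s.max() > 0 else s
    total = s.sum()
    if total <= 0:
        return 0.0
    p = s / total
    return float(-np.sum(p * np.log2(p)))


def renyi_entropy(x: np.ndarray, bins: int = 10, alpha: float = 2.0) -> float:
    """Renyi entropy (1/(1-alpha)) log2 sum(p^alpha) on the histogram."""
    if alpha == 1:
        raise ValueError("alpha = 1 is the Shannon limit; use shannon_entropy")
    p = _hist_probs(np.asarray(x, dtype=float), bins)
    return float(np.log2(np.sum(p**alpha)) / (1.0 - alpha))


def tsallis_entropy(x: np.ndarray, bins: int = 10, q: float = 2.0) -> float:
    """Tsallis entropy (1/(q-1)) (1 - sum(p^q)) on the histogram."""
    if q == 1:
        raise ValueError("q = 1 is the Shannon limit; use shannon_entropy")
    p = _hist_probs(np.asarray(x, dtype=float), bins)
    return float((1.0 - np.sum(p**q)) / (q - 1.0))


def extropy(x: np.ndarray, bins: int = 10) -> float:
    """Extropy: -sum (1-p) log2(1-p) over the histogram bins."""
    p = _hist_probs(np.asarray(x, dtype=float), bins)
    q = 1.0 - p[p < 1.0]
    return float(-np.sum(q * np.log2(q)))


@dataclasses.dataclass
class EntropyConfig:
    """Parameters of the 13-feature bank (defaults are community-standard)."""

    histogram_bins: int = 10
    embed_dim: int = 2
    tolerance_factor: float = 0.2
    permutation_order: int = 3
    permutation_delay: int = 1
    svd_order: int = 3
    svd_delay: int = 1
    renyi_alpha: float = 2.0
    tsallis_q: float = 2.0
    fs: float = 500.0
    feature_list: tuple[str, ...] = (
        "shannon",
        "approximate",
        "sample",
        "permutation",
        "spectral",
        "svd",
        "renyi",
        "tsallis",
        "extropy",
        "renyi_half",
        "tsallis_half",
        "permutation_o4",
        "approximate_m3",
    )

    def __post_init__(self) -> None:
        if self.histogram_bins < 2 or self.embed_dim < 1:
            raise ValueError("bins >= 2 and embed_dim >= 1 required")
        if self.tolerance_factor <= 0:
            raise ValueError("tolerance_factor must be positive")
        if self.permutation_order < 2:
            raise ValueError("permutation_order >= 2 required")
        if self.renyi_alpha == 1 or self.tsallis_q == 1:
            raise ValueError("alpha/q = 1 degenerate to Shannon entropy")

    def n_features(self) -> int:
        return len(self.feature_list)


_FEATURES: dict[str, Callable[[np.ndarray, EntropyConfig], float]] = {
    "shannon": lambda x, c: shannon_entropy(x, c.histogram_bins),
    "approximate": lambda x, c: approximate_entropy(x, c.embed_dim, c.tolerance_factor),
    "sample": lambda x, c: sample_entropy(x, c.embed_dim, c.tolerance_factor),
    "permutation": lambda x, c: permutation_entropy(x, c.permutation_order, c.permutation_delay),
    "spectral": lambda x, c: spectral_entropy(x, c.fs),
    "svd": lambda x, c: svd_entropy(x, c.svd_order, c.svd_delay),
    "renyi": lambda x, c: renyi_entropy(x, c.histogram_bins, c.renyi_alpha),
    "tsallis": lambda x, c: tsallis_entropy(x, c.histogram_bins, c.tsallis_q),
    "extropy": lambda x, c: extropy(x, c.histogram_bins),
    "renyi_half": lambda x, c: renyi_entropy(x, c.histogram_bins, 0.5),
    "tsallis_half": lambda x, c: tsallis_entropy(x, c.histogram_bins, 0.5),
    "permutation_o4": lambda x, c: permutation_entropy(x, 4, c.permutation_delay),
    "approximate_m3": lambda x, c: approximate_entropy(x, 3, c.tolerance_factor),
}


def lead_features(x: np.ndarray, cfg: EntropyConfig | None = None) -> np.ndarray:
    """The 13-feature vector of one lead, in ``cfg.feature_list`` order."""
    cfg = cfg or EntropyConfig()
    return np.array([_FEATURES[name](x, cfg) for name in cfg.feature_list])


def feature_vector(signal: np.ndarray, cfg: EntropyConfig | None = None) -> np.ndarray:
    """Lead-major concatenation of per-lead features (156-dim for 12 leads).

    Works for any segment length with enough samples for the embeddings
    (both L = 5000 raw records and L = 100 QRS segments).
    """
    cfg = cfg or EntropyConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 2:
        raise ValueError("expected a (n_leads, L) matrix")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    return np.concatenate([lead_features(lead, cfg) for lead in signal])


def feature_names(n_leads: int = 12, cfg: EntropyConfig | None = None) -> list[str]:
    """Column names in feature_vector order: lead{i}_{feature}."""
    cfg = cfg or EntropyConfig()
    return [f"lead{i}_{name}" for i in range(n_leads) for name in cfg.feature_list]
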