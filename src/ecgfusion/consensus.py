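"""Multi-detector, multi-lead R-peak consensus.

Every detector runs on every lead (72 candidate lists for the full
six-detector bank on 12 leads).  The beat count ``n_R`` is the median of the
72 per-(detector, lead) cardinalities; the pooled candidate indices are then
clustered with one-dimensional k-means at k = n_R, and the rounded cluster
centers are the consensus R-peak positions.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np

from .data_io import EcgRecord
from .detectors import DetectorBank

logger = logging.getLogger(__name__)


class DegenerateRecordError(ValueError):
    """No usable detections: beat counting/localization is impossible."""


@dataclasses.dataclass
class DetectionSet:
    """Candidate R-peak indices per (detector name, lead index)."""

    hits: dict[tuple[str, int], np.ndarray]

    def cardinalities(self) -> list[int]:
        return [len(v) for v in self.hits.values()]

    def pooled(self) -> np.ndarray:
        """All candidate indices from all entries as one 1-D point set."""
        arrays = [v for v in self.hits.values() if len(v)]
        if not arrays:
            return np.array([], dtype=int)
        return np.sort(np.concatenate(arrays))

    def __len__(self) -> int:
        return len(self.hits)


@dataclasses.dataclass
class ConsensusResult:
    n_R: int
    positions: np.ndarray  # sorted sample indices, len == n_R
    bpm: float


def run_detectors(record: EcgRecord, bank: DetectorBank) -> DetectionSet:
    """Run every detector on every lead independently.

    A detector that raises on a lead contributes an empty entry (logged);
    the entry still participates in the count median with cardinality 0,
    mirroring the robustness rationale of aggregating many sources.
    """
    hits: dict[tuple[str, int], np.ndarray] = {}
    for name, func in bank.items().items():
        for lead in range(record.signal.shape[0]):
            try:
                idx = np.asarray(func(record.signal[lead], record.fs), dtype=int)
            except Exception:
                logger.warning("detector %s failed on lead %d of %s",
                               name, lead, record.record_id, exc_info=True)
                idx = np.array([], dtype=int)
            hits[(name, lead)] = np.sort(idx)
    return DetectionSet(hits)


def consensus_count(detections: DetectionSet) -> int:
    """Median of the per-entry candidate counts, rounded half up when even.

    The classical median of an odd-length sorted list is its middle element;
    for an even number of entries (72 for the full bank) the mean of the two
    middle order statistics is rounded half up so that k-means receives an
    integer k.
    """
    cards = sorted(detections.cardinalities())
    if not cards:
        raise DegenerateRecordError("empty detection set")
    n = len(cards)
    if n % 2 == 1:
        med = float(cards[n // 2])
    else:
        med = (cards[n // 2 - 1] + cards[n // 2]) / 2.0
    n_r = int(math.floor(med + 0.5))
    if n_r < 1:
        raise DegenerateRecordError("median beat count is zero")
    return n_r


def _kmeans_1d(points: np.ndarray, k: int, max_iter: int = 300) -> np.ndarray:
    """Deterministic 1-D Lloyd's algorithm.

    Centers start at the (2i+1)/(2k) quantiles of the point set; iteration
    stops when assignments are stable.  An emptied cluster is re-seeded at
    the point farthest from its nearest center.
    """
    points = np.asarray(points, dtype=float)
    centers = np.quantile(points, (2 * np.arange(k) + 1) / (2 * k))
    assign = np.full(len(points), -1)
    for _ in range(max_iter):
        dist = np.abs(points[:, None] - centers[None, :])
        new_assign = np.argmin(dist, axis=1)
        for c in range(k):
            if not np.any(new_assign == c):
                farthest = int(np.argmax(dist.min(axis=1)))
                centers[c] = points[farthest]
                new_assign[farthest] = c
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            members = points[assign == c]
            if len(members):
                centers[c] = members.mean()
    return np.sort(centers)


def localize_rpeaks(detections: DetectionSet, n_R: int) -> np.ndarray:
    """Cluster the pooled candidate indices with k = n_R; centers -> peaks."""
    points = detections.pooled()
    if len(points) < n_R:
        raise DegenerateRecordError(
            f"{len(points)} pooled candidates < n_R = {n_R}"
        )
    centers = _kmeans_1d(points, n_R)
    positions = np.round(centers).astype(int)
    # rounding can merge near-coincident centers; restore strict monotonicity
    for i in range(1, len(positions)):
        if positions[i] <= positions[i - 1]:
            positions[i] = positions[i - 1] + 1
    return positions


def estimate_bpm(n_R: int, duration_s: float) -> float:
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    return n_R * 60.0 / duration_s


def compute_consensus(record: EcgRecord, bank: DetectorBank | None = None) -> ConsensusResult:
    """Full consensus pass on one record: detect, count, localize."""
    bank = bank or DetectorBank.default()
    detections = run_detectors(record, bank)
    n_r = consensus_count(detections)
    positions = localize_rpeaks(detections, n_r)
    return ConsensusResult(n_r, positions, estimate_bpm(n_r, record.duration_s))


def count_mae(predicted_counts: Sequence[int], true_counts: Sequence[int]) -> float:
    """Mean absolute error of beat counts across records."""
    if len(predicted_counts) != len(true_counts):
        raise ValueError("count lists must have equal length")
    p = np.asarray(predicted_counts, dtype=float)
    t = np.asarray(true_counts, dtype=float)
    return float(np.mean(np.abs(p - t)))
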