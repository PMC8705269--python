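"""Beat segmentation: cut at inter-peak midpoints, drop edges, resample.

A record with consensus peaks p_1 < ... < p_n is partitioned at the midpoints
floor((p_j + p_{j+1}) / 2) into n intervals (half-open, so the retained
intervals plus the discarded edges exactly reconstruct the record).  The
first and last intervals are discarded, leaving n - 2 segments each holding
exactly one R peak near its center; every segment is then linearly resampled
to 100 samples per lead, keeping the original-length/100 ratio as metadata.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .consensus import ConsensusResult
from .data_io import EcgRecord

SEGMENT_LEN = 100


@dataclasses.dataclass
class QrsSegment:
    """One resampled beat: a (12, 100) matrix plus provenance metadata."""

    beat: np.ndarray
    resample_ratio: float  # original interval length / 100; >1 means compression
    source_interval: tuple[int, int]  # half-open [start, end) in original samples
    r_peak_original: int

    def __post_init__(self) -> None:
        if self.beat.shape[1] != SEGMENT_LEN:
            raise ValueError(f"beat must have {SEGMENT_LEN} columns")
        start, end = self.source_interval
        if not start <= self.r_peak_original < end:
            raise ValueError("R peak outside source interval")


@dataclasses.dataclass
class SegmentedRecord:
    segments: list[QrsSegment]
    bpm: float
    record_id: str = ""
    usable: bool = True

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def beats_array(self) -> np.ndarray:
        """Stack of beats, shape (n_segments, 12, 100)."""
        return np.stack([s.beat for s in self.segments])


def cut_points(positions: Sequence[int]) -> np.ndarray:
    """Midpoints between consecutive peaks: floor((p_j + p_{j+1}) / 2)."""
    positions = np.asarray(positions, dtype=int)
    if len(positions) < 2:
        raise ValueError("need at least 2 peak positions to cut")
    return (positions[:-1] + positions[1:]) // 2


def extract_segments(
    record: EcgRecord, positions: Sequence[int]
) -> tuple[list[tuple[int, int, int]], bool]:
    """Partition at midpoints, drop the first and last interval.

    Returns (intervals, usable) where each interval is (start, end, r_peak)
    with a half-open [start, end) span holding exactly one peak.  Fewer than
    3 peaks leaves no interior interval: the record is flagged unusable.
    """
    positions = np.asarray(positions, dtype=int)
    n = record.signal.shape[1]
    if np.any(positions < 0) or np.any(positions >= n):
        raise ValueError("peak positions outside record")
    if len(positions) < 3:
        return [], False
    mids = cut_points(positions)
    bounds = np.r_[0, mids, n]  # len(positions) + 1 boundaries
    intervals = [
        (int(bounds[j]), int(bounds[j + 1]), int(positions[j]))
        for j in range(1, len(positions) - 1)
    ]
    return intervals, True


def resample_segment(
    interval_signal: np.ndarray,
    source_interval: tuple[int, int] = (0, 0),
    r_peak: int | None = None,
) -> QrsSegment:
    """Linearly interpolate each lead onto 100 equally spaced points.

    Endpoints are preserved; the resampling ratio is L/100 where L is the
    original interval length.
    """
    sig = np.asarray(interval_signal, dtype=float)
    length = sig.shape[1]
    if length < 2:
        raise ValueError("interval too short to resample")
    xp = np.arange(length)
    xq = np.linspace(0, length - 1, SEGMENT_LEN)
    beat = np.stack([np.interp(xq, xp, lead) for lead in sig])
    start, end = source_interval
    if end <= start:
        start, end = 0, length
    if r_peak is None:
        r_peak = start
    return QrsSegment(beat, length / SEGMENT_LEN, (start, end), int(r_peak))


def segment_record(record: EcgRecord, consensus: ConsensusResult) -> SegmentedRecord:
    """Cut, drop edges and resample one record using its consensus peaks."""
    intervals, usable = extract_segments(record, consensus.positions)
    segments = [
        resample_segment(record.signal[:, start:end], (start, end), peak)
        for start, end, peak in intervals
    ]
    return SegmentedRecord(segments, consensus.bpm, record.record_id, usable)
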