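"""Record containers, metadata filtering, synthetic ECG and WFDB I/O.

Records are 12-lead, 10 s, 500 Hz clinical ECGs (5000 samples per lead, in
millivolts) annotated with one of five diagnostic superclasses (NORM, CD,
STTC, MI, HYP) and one of twenty subclasses.  Real data arrives as WFDB
format-16 signal files plus two CSV metadata tables (record list with a
label-code dictionary column, and a code -> superclass/subclass mapping);
synthetic data with exact ground-truth R-peak positions is generated
in-package so the whole pipeline is testable without any download.
"""

from __future__ import annotations

import ast
import csv
import dataclasses
import os
from typing import Iterable, Mapping, Sequence

import numpy as np

N_LEADS = 12
FS = 500
DURATION_S = 10
N_SAMPLES = FS * DURATION_S

SUPERCLASSES = ("NORM", "CD", "STTC", "MI", "HYP")

#: diagnostic superclass -> subclasses (the 20-subclass scheme)
CLASS_TO_SUBCLASSES = {
    "NORM": ["NORM"],
    "CD": ["LAFB/LPFB", "IRBBB", "CLBBB", "CRBBB", "IVCD", "_AVB", "WPW", "ILBBB"],
    "STTC": ["STTC", "NST_", "ISCA", "ISC_", "ISCI"],
    "MI": ["AMI", "IMI", "LMI"],
    "HYP": ["LVH", "LAO/LAE", "RAO/RAE"],
}
SUBCLASS_TO_CLASS = {
    sub: sup for sup, subs in CLASS_TO_SUBCLASSES.items() for sub in subs
}

LEAD_NAMES = ("I", "II", "III", "AVR", "AVL", "AVF",
              "V1", "V2", "V3", "V4", "V5", "V6")

# relative per-lead projection of the beat template; AVR is inverted, as in
# a physiological frontal-plane axis around +60 degrees
DEFAULT_LEAD_SCALE = np.array(
    [0.70, 1.00, 0.50, -0.90, 0.45, 0.80, 0.35, 0.60, 0.85, 1.00, 0.90, 0.75]
)


class FormatError(ValueError):
    """Raised when a record on disk violates the 12-lead / 500 Hz contract."""


@dataclasses.dataclass
class EcgRecord:
    """One 12-lead ECG: a (12, 5000) float matrix in mV at 500 Hz."""

    record_id: str
    signal: np.ndarray
    fs: int = FS
    superclass: str | None = None
    subclass: str | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[0] != N_LEADS:
            raise FormatError(
                f"expected {N_LEADS} leads, got shape {self.signal.shape}"
            )
        if self.signal.shape[1] != self.fs * DURATION_S:
            raise FormatError(
                f"expected {self.fs * DURATION_S} samples at {self.fs} Hz, "
                f"got {self.signal.shape[1]}"
            )
        if not np.all(np.isfinite(self.signal)):
            raise FormatError("signal contains non-finite values")

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.fs

    @property
    def binary_label(self) -> int:
        """0 for NORM, 1 for any abnormal superclass."""
        return 0 if self.superclass == "NORM" else 1


@dataclasses.dataclass
class RecordMetadata:
    """One metadata row: label codes with likelihoods, resolved classes."""

    record_id: str
    label_codes: dict[str, float] = dataclasses.field(default_factory=dict)
    superclass: str | None = None
    subclass: str | None = None
    assigned: bool = False


def filter_metadata(
    rows: Sequence[RecordMetadata],
    code_map: Mapping[str, tuple[str, str]],
    min_subclass_size: int = 20,
) -> list[RecordMetadata]:
    """Apply the label-certainty and subclass-population filters.

    A record survives iff it carries at least one diagnostic code at exactly
    100% likelihood, all its 100%-likelihood diagnostic codes resolve to a
    single (superclass, subclass) pair, and that subclass has at least
    ``min_subclass_size`` surviving members.  Survivors get ``superclass``,
    ``subclass`` and ``assigned`` filled in.  Records with multiple
    100%-certain superclasses (or subclasses) are dropped: the surviving set
    must assign exactly one class and one subclass per record, and the source
    labeling scheme offers no tie-break.

    ``code_map`` maps a diagnostic label code to its (superclass, subclass);
    codes absent from the map (non-diagnostic annotations) are ignored.
    """
    certain: list[RecordMetadata] = []
    for row in rows:
        pairs = {
            code_map[c]
            for c, lik in row.label_codes.items()
            if lik == 100 and c in code_map
        }
        supers = {p[0] for p in pairs}
        subs = {p[1] for p in pairs}
        if len(supers) == 1 and len(subs) == 1:
            (sup,), (sub,) = supers, subs
            certain.append(
                dataclasses.replace(row, superclass=sup, subclass=sub, assigned=True)
            )
    counts: dict[str, int] = {}
    for row in certain:
        counts[row.subclass] = counts.get(row.subclass, 0) + 1
    return [r for r in certain if counts[r.subclass] >= min_subclass_size]


def load_ptbxl_metadata(
    database_csv: str, statements_csv: str
) -> tuple[list[RecordMetadata], dict[str, tuple[str, str]]]:
    """Read PTB-XL-dialect metadata CSVs.

    ``database_csv`` has one row per record with an ``scp_codes`` column
    holding a python-dict literal of code -> likelihood; ``statements_csv``
    maps codes to ``diagnostic_class`` / ``diagnostic_subclass`` (only rows
    with ``diagnostic == 1`` participate).
    """
    import pandas as pd

    db = pd.read_csv(database_csv, index_col=0)
    scp = pd.read_csv(statements_csv, index_col=0)
    diag = scp[scp.get("diagnostic", 0) == 1]
    code_map = {
        str(code): (str(r["diagnostic_class"]), str(r["diagnostic_subclass"]))
        for code, r in diag.iterrows()
        if isinstance(r.get("diagnostic_class"), str)
        and isinstance(r.get("diagnostic_subclass"), str)
    }
    rows = [
        RecordMetadata(record_id=str(idx), label_codes=ast.literal_eval(r["scp_codes"]))
        for idx, r in db.iterrows()
    ]
    return rows, code_map


# ---------------------------------------------------------------------------
# synthetic ECG


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic 12-lead record.

    ``bpm_mean`` sets the beat rate (the clean 10 s record then carries
    ``round(bpm_mean / 6)`` beats); ``bpm_jitter`` perturbs each inter-beat
    interval (beats/min, s.d.); ``qrs_width_ms`` is the approximate full width
    of the R deflection; ``t_amp`` the T-wave amplitude in mV; ``noise_sd``
    additive Gaussian noise in mV.
    """

    bpm_mean: float = 60.0
    bpm_jitter: float = 0.0
    qrs_width_ms: float = 80.0
    lead_scale: np.ndarray = dataclasses.field(
        default_factory=lambda: DEFAULT_LEAD_SCALE.copy()
    )
    noise_sd: float = 0.0
    t_amp: float = 0.25
    class_id: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 30 <= self.bpm_mean <= 200:
            raise ValueError(f"bpm_mean {self.bpm_mean} outside [30, 200]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.lead_scale = np.asarray(self.lead_scale, dtype=float)
        if self.lead_scale.shape != (N_LEADS,):
            raise ValueError("lead_scale must have one entry per lead")


def _beat_template(t: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    """Template voltage at times ``t`` (seconds relative to the R peak).

    ``qrs_width_ms`` is the approximate Q-to-S duration: the R bump s.d. is
    width/8 (FWHM about 0.3 width) and the Q/S dips sit at +-0.4 width.
    """
    w = spec.qrs_width_ms / 1000.0
    r_sd = w / 8.0
    out = np.exp(-0.5 * (t / r_sd) ** 2)  # R, amplitude 1 mV
    waves = (
        (-0.200 - 0.4 * w, 0.12, 0.030),          # P
        (-0.4 * w, -0.10, 0.15 * w),              # Q
        (0.4 * w, -0.18, 0.15 * w),               # S
        (0.280 + 0.4 * w, spec.t_amp, 0.060),     # T
    )
    for off, amp, sd in waves:
        out += amp * np.exp(-0.5 * ((t - off) / sd) ** 2)
    return out


def generate_synthetic_record(
    spec: SyntheticSpec, record_id: str = "synthetic"
) -> tuple[EcgRecord, np.ndarray]:
    """Build one record plus its exact R-peak sample indices.

    Beats are evenly spaced at ``bpm_mean`` (clean count round(bpm_mean/6) in
    10 s), each inter-beat interval perturbed by ``bpm_jitter``.  Each lead is
    the per-lead scaled P-QRS-T template plus Gaussian noise, quantized to
    1/1000 mV (a 16-bit ADC at gain 1000) so that WFDB round-trips are exact.
    Deterministic given ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n_beats = int(round(spec.bpm_mean / 6.0))
    period = FS * 60.0 / spec.bpm_mean
    start = (N_SAMPLES - (n_beats - 1) * period) / 2.0
    centers = start + np.arange(n_beats) * period
    if spec.bpm_jitter > 0:
        # jitter each interval: d(period)/d(bpm) = -fs*60/bpm^2
        sd = FS * 60.0 * spec.bpm_jitter / spec.bpm_mean**2
        centers = centers + np.cumsum(rng.normal(0.0, sd, n_beats))
    margin = int(0.06 * FS)
    centers = centers[(centers >= margin) & (centers < N_SAMPLES - margin)]
    rpeaks = np.round(centers).astype(int)

    t = np.arange(N_SAMPLES) / FS
    base = np.zeros(N_SAMPLES)
    for c in rpeaks:
        base += _beat_template(t - c / FS, spec)
    signal = spec.lead_scale[:, None] * base[None, :]
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    signal = np.round(signal * 1000.0) / 1000.0
    classes = list(SUPERCLASSES)
    sup = classes[spec.class_id % len(classes)]
    rec = EcgRecord(record_id, signal, FS, superclass=sup,
                    subclass=CLASS_TO_SUBCLASSES[sup][0])
    return rec, rpeaks


def class_spec(class_id: int, rng: np.random.Generator,
               noise_sd: float = 0.0) -> SyntheticSpec:
    """Draw a record spec for a synthetic diagnostic class.

    Classes differ in QRS width (wider, bundle-branch-block-like complexes
    for higher ids), T-wave amplitude and heart-rate range, which makes a
    small multi-class problem learnably separable while every record keeps
    realistic beat morphology.
    """
    bpm = float(rng.uniform(55 + 5 * class_id, 110 + 5 * class_id))
    return SyntheticSpec(
        bpm_mean=bpm,
        bpm_jitter=0.5,
        qrs_width_ms=80.0 + 25.0 * class_id,
        noise_sd=noise_sd,
        t_amp=0.25 + 0.15 * class_id,
        class_id=class_id,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
    )


def synthetic_dataset(
    n_records: int,
    n_classes: int = 2,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> list[tuple[EcgRecord, np.ndarray]]:
    """Generate a balanced labeled dataset of (record, true_rpeaks) pairs."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_records):
        cid = i % n_classes
        spec = class_spec(cid, rng, noise_sd=noise_sd)
        rec, peaks = generate_synthetic_record(spec, record_id=f"syn{i:05d}")
        out.append((rec, peaks))
    return out


# ---------------------------------------------------------------------------
# WFDB format-16 I/O (16-bit little-endian, interleaved, gain in ADU/mV)

_GAIN = 1000
_FMT = 16


def write_record(record: EcgRecord, directory: str) -> str:
    """Write ``record`` as a WFDB format-16 .hea/.dat pair; returns basename."""
    os.makedirs(directory, exist_ok=True)
    base = os.path.join(directory, record.record_id)
    adc = np.round(record.signal * _GAIN).astype(np.int16)
    lines = [f"{record.record_id} {N_LEADS} {record.fs} {record.signal.shape[1]}"]
    for i in range(N_LEADS):
        checksum = int(np.int16(adc[i].astype(np.int64).sum() % 65536))
        lines.append(
            f"{record.record_id}.dat {_FMT} {_GAIN}/mV 16 0 "
            f"{int(adc[i, 0])} {checksum} 0 {LEAD_NAMES[i]}"
        )
    if record.superclass:
        lines.append(f"# superclass: {record.superclass}")
    if record.subclass:
        lines.append(f"# subclass: {record.subclass}")
    with open(base + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    adc.T.tofile(base + ".dat")  # sample-major interleave
    return base


def load_record(
    path: str, metadata: RecordMetadata | None = None, expected_fs: int = FS
) -> EcgRecord:
    """Read a WFDB format-16 record written by :func:`write_record`.

    ``path`` is the WFDB basename (no extension).  Raises ``FileNotFoundError``
    for missing files, :class:`FormatError` for a lead count other than 12 or
    a sampling rate other than ``expected_fs``.
    """
    hea = path + ".hea"
    if not os.path.exists(hea):
        raise FileNotFoundError(hea)
    comments: dict[str, str] = {}
    with open(hea) as fh:
        lines = []
        for raw in fh:
            raw = raw.strip()
            if not raw:
                continue
            if raw.startswith("#"):
                if ":" in raw:
                    k, v = raw[1:].split(":", 1)
                    comments[k.strip()] = v.strip()
                continue
            lines.append(raw)
    name, nsig, fs, nsamp = lines[0].split()[:4]
    nsig, fs, nsamp = int(nsig), int(float(fs)), int(nsamp)
    if nsig != N_LEADS:
        raise FormatError(f"record has {nsig} leads, expected {N_LEADS}")
    if fs != expected_fs:
        raise FormatError(f"record sampled at {fs} Hz, expected {expected_fs}")
    gains = []
    for line in lines[1 : 1 + nsig]:
        fields = line.split()
        if int(fields[1]) != _FMT:
            raise FormatError(f"unsupported WFDB format {fields[1]}")
        gains.append(float(fields[2].split("/")[0].split("(")[0]))
    dat = path + ".dat"
    if not os.path.exists(dat):
        raise FileNotFoundError(dat)
    adc = np.fromfile(dat, dtype="<i2")
    if adc.size != nsig * nsamp:
        raise FormatError(f"signal file holds {adc.size} samples, expected {nsig * nsamp}")
    signal = adc.reshape(nsamp, nsig).T / np.asarray(gains)[:, None]
    rec_id = metadata.record_id if metadata else name
    return EcgRecord(
        rec_id,
        signal,
        fs,
        superclass=(metadata.superclass if metadata else comments.get("superclass")),
        subclass=(metadata.subclass if metadata else comments.get("subclass")),
    )


def write_truth_csv(
    path: str, entries: Iterable[tuple[str, Sequence[int], int]]
) -> None:
    """Write fixture ground truth: record_id, comma-joined R-peaks, class_id."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["record_id", "rpeaks", "class_id"])
        for rec_id, peaks, cid in entries:
            w.writerow([rec_id, ",".join(str(int(p)) for p in peaks), cid])


def read_truth_csv(path: str) -> list[tuple[str, np.ndarray, int]]:
    """Read the fixture ground-truth CSV written by :func:`write_truth_csv`."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            peaks = np.array(
                [int(p) for p in row["rpeaks"].split(",") if p], dtype=int
            )
            out.append((row["record_id"], peaks, int(row["class_id"])))
    return out
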