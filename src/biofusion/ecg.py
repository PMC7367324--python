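"""ECG preprocessing: raw records -> normalized QRS-complex sequences.

The pipeline turns a single-lead voltage series into the model input: the
record is brought to 500 Hz, R peaks are located with a Pan-Tompkins-style
detector, a 300-sample window (150 samples either side of each R peak) is
cropped and min-max normalized, and consecutive complexes are grouped in
threes into fixed-shape sequences.  A 20 s record at typical resting heart
rates yields at least 15 complexes and hence at least 5 sequences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

TARGET_RATE = 500.0
QRS_LENGTH = 300          # samples per complex (150 before + 150 after the R peak)
HALF_WINDOW = QRS_LENGTH // 2
SEQUENCE_LENGTH = 3       # complexes per input sequence
REFRACTORY_S = 0.2        # minimum R-R separation enforced by the detector


@dataclass
class EcgRecord:
    """A raw single-lead ECG voltage series."""

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    lead: str = "I"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate


@dataclass
class QrsComplex:
    """One min-max-normalized 300-sample beat window centred on an R peak."""

    values: np.ndarray
    r_peak_index: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (QRS_LENGTH,):
            raise ValueError(f"QRS complex must have exactly {QRS_LENGTH} samples")


@dataclass
class EcgSequence:
    """Three stacked QRS complexes, shape (3, 300) — the model input x_e."""

    complexes: np.ndarray
    subject_id: str = ""
    gender: str | None = None

    def __post_init__(self):
        self.complexes = np.asarray(self.complexes, dtype=np.float64)
        if self.complexes.shape != (SEQUENCE_LENGTH, QRS_LENGTH):
            raise ValueError(
                f"sequence must have shape ({SEQUENCE_LENGTH}, {QRS_LENGTH})"
            )


def resample_record(record: EcgRecord, target_rate: float = TARGET_RATE) -> EcgRecord:
    """Resample a record to ``target_rate`` Hz (Fourier method).

    Duration is preserved to within one sample period.  A record already at
    the target rate is returned as an identical copy.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if len(record.samples) == 0:
        raise ValueError("cannot resample an empty signal")
    if record.sampling_rate == target_rate:
        return EcgRecord(record.samples.copy(), target_rate, record.subject_id,
                         record.lead, dict(record.meta))
    n_out = int(round(len(record.samples) * target_rate / record.sampling_rate))
    resampled = sps.resample(record.samples, n_out)
    return EcgRecord(resampled, target_rate, record.subject_id, record.lead,
                     dict(record.meta))


def detect_r_peaks(record: EcgRecord) -> np.ndarray:
    """Locate R peaks (sample indices, strictly increasing).

    Pan-Tompkins-style: 5-15 Hz band-pass, squaring, 150 ms moving-window
    integration, thresholding at a fraction of the robust signal ceiling,
    then refinement to the local maximum of the band-passed signal.  A
    200 ms refractory period suppresses double detections.  Returns an
    empty array for flat or sub-threshold signals.
    """
    fs = record.sampling_rate
    x = record.samples
    if len(x) < int(0.5 * fs):
        return np.array([], dtype=int)
    if np.ptp(x) == 0:
        return np.array([], dtype=int)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    sq = band**2
    win = max(1, int(0.150 * fs))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    ceiling = np.percentile(integ, 99)
    if ceiling <= 0:
        return np.array([], dtype=int)
    distance = max(1, int(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(integ, height=0.25 * ceiling, distance=distance)

    # refine each candidate to the nearby band-passed maximum (R apex)
    half = int(0.075 * fs)
    refined = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        refined.append(lo + int(np.argmax(band[lo:hi])))
    refined = sorted(set(refined))

    # enforce refractory after refinement: keep the larger of close pairs
    peaks: list[int] = []
    for r in refined:
        if peaks and r - peaks[-1] < distance:
            if band[r] > band[peaks[-1]]:
                peaks[-1] = r
        else:
            peaks.append(r)
    return np.array(peaks, dtype=int)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Affine map of a vector onto [0, 1]; a constant vector maps to zeros."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot normalize an empty vector")
    lo = values.min()
    rng = values.max() - lo
    if rng == 0:
        return np.zeros_like(values)
    return (values - lo) / rng


def extract_qrs(record: EcgRecord, r_peak: int) -> QrsComplex | None:
    """Crop the normalized 300-sample window ``[r_peak-150, r_peak+150)``.

    Returns ``None`` (the complex is skipped) when the window does not fit
    inside the record.
    """
    start = r_peak - HALF_WINDOW
    stop = r_peak + HALF_WINDOW
    if start < 0 or stop > len(record.samples):
        return None
    window = record.samples[start:stop]
    return QrsComplex(minmax_normalize(window), r_peak)


def group_complexes(
    complexes: list[QrsComplex],
    subject_id: str = "",
    gender: str | None = None,
    mode: str = "consecutive",
    n_sequences: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[EcgSequence]:
    """Group complexes into 3-timestep sequences.

    ``mode='consecutive'`` (default) takes non-overlapping groups of three
    in temporal order, dropping the remainder.  ``mode='random'`` draws
    ``n_sequences`` unordered triples without replacement within each
    triple (an expansion useful for building large per-subject sample
    pools from a limited beat inventory).
    """
    if len(complexes) < SEQUENCE_LENGTH:
        logger.warning(
            "only %d complexes available; need %d for one sequence",
            len(complexes), SEQUENCE_LENGTH,
        )
        return []
    if mode == "consecutive":
        n = len(complexes) // SEQUENCE_LENGTH
        return [
            EcgSequence(
                np.stack([c.values for c in complexes[3 * i : 3 * i + 3]]),
                subject_id, gender,
            )
            for i in range(n)
        ]
    if mode == "random":
        if rng is None or n_sequences is None:
            raise ValueError("random mode requires rng and n_sequences")
        out = []
        for _ in range(n_sequences):
            idx = rng.choice(len(complexes), size=SEQUENCE_LENGTH, replace=False)
            out.append(
                EcgSequence(np.stack([complexes[i].values for i in idx]),
                            subject_id, gender)
            )
        return out
    raise ValueError(f"unknown grouping mode: {mode!r}")


def record_to_sequences(record: EcgRecord, **group_kwargs) -> list[EcgSequence]:
    """Full pipeline: resample -> detect -> crop+normalize -> group."""
    rec = resample_record(record, TARGET_RATE)
    peaks = detect_r_peaks(rec)
    complexes = [c for p in peaks if (c := extract_qrs(rec, p)) is not None]
    gender = rec.meta.get("gender")
    return group_complexes(complexes, rec.subject_id, gender, **group_kwargs)


# ---------------------------------------------------------------------------
# I/O: plain-text records and compressed sequence bundles


def read_record_txt(path: str | Path) -> EcgRecord:
    """Read a one-column delimited numeric file with a JSON sidecar.

    The sidecar ``<stem>.json`` must provide ``sampling_rate`` and may
    provide ``subject_id``, ``lead``, ``gender`` and ``age``.
    """
    path = Path(path)
    samples = np.loadtxt(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sampling-rate sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    rate = float(meta.pop("sampling_rate"))
    return EcgRecord(samples, rate, str(meta.pop("subject_id", path.stem)),
                     str(meta.pop("lead", "I")), meta)


def write_record_txt(record: EcgRecord, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path, record.samples, fmt="%.6f")
    meta = {"sampling_rate": record.sampling_rate, "subject_id": record.subject_id,
            "lead": record.lead, **record.meta}
    path.with_suffix(".json").write_text(json.dumps(meta))


def write_sequences(sequences: list[EcgSequence], path: str | Path) -> None:
    """Serialize sequences as a compressed array + JSON metadata sidecar."""
    path = Path(path)
    arr = np.stack([s.complexes for s in sequences])
    np.savez_compressed(path, sequences=arr)
    meta = [{"subject_id": s.subject_id, "gender": s.gender} for s in sequences]
    path.with_suffix(".json").write_text(json.dumps(meta))


def read_sequences(path: str | Path) -> list[EcgSequence]:
    path = Path(path)
    npz = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    arr = np.load(npz)["sequences"]
    meta = json.loads(path.with_suffix(".json").read_text())
    return [EcgSequence(a, m["subject_id"], m["gender"]) for a, m in zip(arr, meta)]
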