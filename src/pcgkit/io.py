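"""Reading and writing heart-sound recordings and dataset manifests.

All recordings are normalized on ingestion to the pipeline's canonical form:
mono, dimensionless amplitude in [-1, 1], resampled to 2000 Hz. Labels are
the strings ``"normal"`` / ``"abnormal"`` / ``"unknown"``; the PhysioNet
convention of ``-1`` (normal) / ``1`` (abnormal) is mapped at read time.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

#: Canonical internal sampling rate (Hz). Every record is resampled to this
#: on ingestion; all downstream defaults (filter bands, MFCC analysis)
#: assume it.
CANONICAL_RATE_HZ = 2000

VALID_LABELS = ("normal", "abnormal", "unknown")

#: Annotation event names the pipeline understands.
EVENT_NAMES = ("S1", "S2", "S3", "S4", "murmur")

# PhysioNet-2016 reference files use -1 for normal, 1 for abnormal.
_PHYSIONET_LABEL_MAP = {"-1": "normal", "1": "abnormal"}


@dataclass
class PCGRecord:
    """A sampled phonocardiogram trace.

    Parameters
    ----------
    record_id : str
        Unique identifier (typically the file stem).
    samples : ndarray
        Dimensionless amplitude, normalized to [-1, 1].
    sample_rate_hz : int
        Sampling rate; 2000 Hz after ingestion.
    label : str
        ``"normal"``, ``"abnormal"`` or ``"unknown"``.
    annotations : list of (event, time_s)
        Optional ground-truth event markers (S1/S2/S3/S4/murmur), times in
        seconds from record start.
    provenance : list of str
        Human-readable processing history.
    """

    record_id: str
    samples: np.ndarray
    sample_rate_hz: int
    label: str = "unknown"
    annotations: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        dur = self.duration_s
        for event, t in self.annotations:
            if event not in EVENT_NAMES:
                raise ValueError(f"unknown annotation event {event!r}")
            if not (0.0 <= t <= dur):
                raise ValueError(f"annotation {event} at {t} s outside [0, {dur}] s")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    def event_times(self, event: str) -> np.ndarray:
        """Times (s) of all annotations of one event type, sorted."""
        return np.sort([t for e, t in self.annotations if e == event])

    def replace_samples(self, samples, note: str | None = None) -> "PCGRecord":
        """Copy of this record with new samples and an appended provenance note."""
        prov = list(self.provenance) + ([note] if note else [])
        return PCGRecord(self.record_id, np.asarray(samples, float),
                         self.sample_rate_hz, self.label,
                         list(self.annotations), prov)


@dataclass
class DatasetManifest:
    """An ordered collection of (record_id, path, label) entries."""

    entries: list  # list of (record_id, Path, label)
    root: Path = Path(".")

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record_ids in manifest: {dupes}")
        for rid, _path, label in self.entries:
            if label not in VALID_LABELS:
                raise ValueError(f"record {rid!r}: unknown label {label!r}")

    def __len__(self):
        return len(self.entries)

    @property
    def class_counts(self) -> dict:
        counts: dict = {}
        for _rid, _path, label in self.entries:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def labels(self) -> list:
        return [label for _rid, _path, label in self.entries]

    def load(self, record_id: str) -> PCGRecord:
        for rid, path, label in self.entries:
            if rid == record_id:
                rec = read_wav(Path(self.root) / path)
                rec.record_id = rid
                rec.label = label
                return rec
        raise KeyError(record_id)

    def iter_records(self):
        for rid, _path, _label in self.entries:
            yield self.load(rid)


def read_wav(path, expected_rate_hz: int = CANONICAL_RATE_HZ) -> PCGRecord:
    """Read a mono PCM WAV file into a canonical :class:`PCGRecord`.

    Samples are scaled to [-1, 1]; if the file rate differs from
    ``expected_rate_hz`` the signal is resampled by polyphase filtering and
    the original rate is recorded in provenance.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rate, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError(
            f"{path.name}: expected a single-channel file, got {data.shape[1]} channels")
    if data.size == 0:
        raise IOError(f"{path.name}: empty WAV file")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:  # float WAV
        samples = data.astype(np.float64)
        peak = np.max(np.abs(samples))
        if peak > 1.0:
            samples = samples / peak
    provenance = [f"read {path.name} at {rate} Hz"]
    if rate != expected_rate_hz:
        frac = Fraction(expected_rate_hz, rate).limit_denominator(1000)
        samples = resample_poly(samples, frac.numerator, frac.denominator)
        provenance.append(f"resampled {rate} -> {expected_rate_hz} Hz")
        rate = expected_rate_hz
    return PCGRecord(path.stem, samples, rate, provenance=provenance)


def write_wav(record: PCGRecord, path) -> Path:
    """Write a record as 16-bit PCM mono WAV. Clipping saturates with a warning."""
    path = Path(path)
    x = np.asarray(record.samples, float)
    if np.max(np.abs(x)) > 1.0:
        warnings.warn(f"{record.record_id}: samples exceed [-1, 1]; saturating")
        x = np.clip(x, -1.0, 1.0)
    data = np.clip(np.round(x * 32768.0), -32768, 32767).astype(np.int16)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(str(path), record.sample_rate_hz, data)
    return path


def _normalize_label(token: str, row_num: int):
    token = token.strip()
    if token in VALID_LABELS:
        return token
    if token in _PHYSIONET_LABEL_MAP:
        return _PHYSIONET_LABEL_MAP[token]
    raise ValueError(f"manifest row {row_num}: unknown label token {token!r}")


def read_manifest(path) -> DatasetManifest:
    """Read a CSV manifest with header ``record_id,path,label``.

    Paths are interpreted relative to the manifest's directory.
    """
    path = Path(path)
    entries = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path.name}: empty manifest")
        header = [h.strip() for h in header]
        if header[:3] != ["record_id", "path", "label"]:
            raise ValueError(
                f"{path.name}: expected header record_id,path,label, got {header}")
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path.name} row {i}: expected 3 columns, got {len(row)}")
            rid, rel, label = row[0].strip(), row[1].strip(), row[2]
            entries.append((rid, Path(rel), _normalize_label(label, i)))
    if not entries:
        raise ValueError(f"{path.name}: manifest has no entries")
    return DatasetManifest(entries, root=path.parent)


def write_manifest(manifest: DatasetManifest, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["record_id", "path", "label"])
        for rid, rel, label in manifest.entries:
            writer.writerow([rid, str(rel), label])
    return path


def read_physionet_layout(records_file, reference_csv) -> DatasetManifest:
    """Adapter for the PhysioNet-2016 layout: a RECORDS file listing record
    names plus a reference CSV of ``name,label`` with labels -1/1."""
    records_file = Path(records_file)
    names = [ln.strip() for ln in records_file.read_text().splitlines() if ln.strip()]
    labels = {}
    with open(reference_csv, newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if len(row) >= 2:
                labels[row[0].strip()] = _normalize_label(row[1], i)
    entries = [(n, Path(n + ".wav"), labels.get(n, "unknown")) for n in names]
    return DatasetManifest(entries, root=records_file.parent)
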