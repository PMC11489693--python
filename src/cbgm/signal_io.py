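"""Reading and writing ECG records, beat annotations, and segment datasets.

Records use the PhysioNet WFDB layout: a text header (``.hea``), a binary
signal file (format 16, little-endian 16-bit integers, samples interleaved
across leads, ``.dat``), and an optional beat annotation file in the MIT
annotation format (``.atr``).  Only the subset of WFDB needed to round-trip
locally written fixtures is implemented; amplitudes are stored with a fixed
ADC gain and exposed in millivolts.

Beat symbols are mapped onto the five beat classes used throughout the
package: N (normal), A (atrial premature), V (premature ventricular
contraction), L (left bundle branch block), R (right bundle branch block).
Any other symbol is outside the classification alphabet and is dropped.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, LeadNotFoundError, SchemaError

__all__ = [
    "CLASSES",
    "ABSENT",
    "BeatAnnotation",
    "AnnotatedRecord",
    "Segment",
    "SegmentDataset",
    "map_symbol",
    "read_record",
    "write_record",
    "read_segments",
    "write_segments",
]

#: Class alphabet, in canonical order (also the confusion-matrix order).
CLASSES: tuple = ("N", "A", "V", "L", "R")

#: Marker for annotation symbols outside the five-class alphabet.
ABSENT = None

# MIT annotation-format beat codes <-> symbols (subset).
_CODE_TO_SYMBOL = {
    1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J", 8: "A",
    9: "S", 10: "E", 11: "j", 12: "/", 13: "Q", 34: "e", 38: "f",
}
_SYMBOL_TO_CODE = {s: c for c, s in _CODE_TO_SYMBOL.items()}
_SKIP = 59  # code whose payload is a 4-byte long interval

_ADC_GAIN = 200.0  # ADC units per millivolt, the MIT-BIH convention
_ADC_RES = 11


def map_symbol(symbol: str):
    """Map an annotation symbol to one of the five beat classes.

    The five literal symbols ``N``, ``A``, ``V``, ``L``, ``R`` map to
    themselves; every other symbol (paced beats, fusion beats, rhythm
    labels, ...) maps to :data:`ABSENT` and is excluded downstream.  Total:
    never raises.
    """
    return symbol if symbol in CLASSES else ABSENT


@dataclass(frozen=True)
class BeatAnnotation:
    """A single annotated beat: the R-peak sample index and its symbol."""

    sample_index: int
    symbol: str

    @property
    def label(self):
        return map_symbol(self.symbol)


@dataclass
class AnnotatedRecord:
    """A multi-lead ECG signal with sampling rate and beat annotations.

    ``signal`` has shape (n_samples, n_leads), amplitudes in mV.  Annotation
    sample indices are 0-based and refer to the R-peak sample.
    """

    record_id: str
    sampling_rate: float
    leads: list
    signal: np.ndarray
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] < self.signal.shape[1] and self.signal.ndim == 2 \
                and len(self.leads) == self.signal.shape[0]:
            self.signal = self.signal.T
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n = self.signal.shape[0]
        for a in self.annotations:
            if not (0 <= a.sample_index < n):
                raise ValueError(
                    f"annotation index {a.sample_index} outside [0, {n})"
                )
        self.annotations = sorted(self.annotations, key=lambda a: a.sample_index)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    def lead(self, which=0) -> np.ndarray:
        """Return one lead as a 1-D array; `which` is an index or lead name."""
        if isinstance(which, str):
            if which not in self.leads:
                raise LeadNotFoundError(f"lead {which!r} not in {self.leads}")
            which = self.leads.index(which)
        if not 0 <= which < self.signal.shape[1]:
            raise LeadNotFoundError(f"lead index {which} out of range")
        return self.signal[:, which]


@dataclass
class Segment:
    """One fixed-length heartbeat pulse (300 samples) with its class label."""

    values: np.ndarray
    label: str
    r_index: int
    record_id: str = ""

    SEGMENT_LENGTH = 300

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.SEGMENT_LENGTH:
            raise ValueError(
                f"segment must have length {self.SEGMENT_LENGTH}, "
                f"got {self.values.size}"
            )
        if self.label not in CLASSES:
            raise ValueError(f"label {self.label!r} not in {CLASSES}")


@dataclass
class SegmentDataset:
    """A list of segments plus per-class counts."""

    segments: list

    @property
    def class_counts(self) -> dict:
        counts = {c: 0 for c in CLASSES}
        for s in self.segments:
            counts[s.label] += 1
        return counts

    def __len__(self):
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def to_arrays(self):
        """Return (X, y) with X of shape (n, 300) and y integer class ids."""
        if not self.segments:
            return np.zeros((0, Segment.SEGMENT_LENGTH)), np.zeros(0, dtype=int)
        X = np.stack([s.values for s in self.segments])
        y = np.array([CLASSES.index(s.label) for s in self.segments])
        return X, y


# --------------------------------------------------------------------------
# WFDB subset I/O
# --------------------------------------------------------------------------

def write_record(record: AnnotatedRecord, directory: str) -> str:
    """Write `record` as a WFDB record (.hea + format-16 .dat [+ .atr])."""
    os.makedirs(directory, exist_ok=True)
    base = os.path.join(directory, record.record_id)
    n_samples, n_leads = record.signal.shape
    adc = np.round(record.signal * _ADC_GAIN).astype(np.int64)
    adc = np.clip(adc, -32768, 32767).astype("<i2")
    with open(base + ".hea", "w") as fh:
        fh.write(
            f"{record.record_id} {n_leads} {record.sampling_rate:g} {n_samples}\n"
        )
        for j, lead in enumerate(record.leads):
            first = int(adc[0, j]) if n_samples else 0
            fh.write(
                f"{record.record_id}.dat 16 {_ADC_GAIN:g} {_ADC_RES} 0 "
                f"{first} 0 0 {lead}\n"
            )
    adc.reshape(-1).tofile(base + ".dat")
    if record.annotations:
        _write_annotations(base + ".atr", record.annotations)
    return base


def _write_annotations(path: str, annotations: Sequence[BeatAnnotation]) -> None:
    buf = io.BytesIO()
    prev = 0
    for a in annotations:
        delta = a.sample_index - prev
        prev = a.sample_index
        if delta > 1023:
            buf.write(int(_SKIP << 10).to_bytes(2, "little"))
            buf.write(((delta >> 16) & 0xFFFF).to_bytes(2, "little"))
            buf.write((delta & 0xFFFF).to_bytes(2, "little"))
            delta = 0
        code = _SYMBOL_TO_CODE.get(a.symbol, 13)  # unknown -> Q
        buf.write(((code << 10) | delta).to_bytes(2, "little"))
    buf.write(b"\x00\x00")
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def _read_annotations(path: str) -> list:
    raw = open(path, "rb").read()
    anns, t, i, pending_skip = [], 0, 0, 0
    while i + 1 < len(raw):
        word = int.from_bytes(raw[i : i + 2], "little")
        i += 2
        code, delta = word >> 10, word & 0x3FF
        if code == 0 and delta == 0:
            break
        if code == _SKIP:
            hi = int.from_bytes(raw[i : i + 2], "little")
            lo = int.from_bytes(raw[i + 2 : i + 4], "little")
            i += 4
            pending_skip += (hi << 16) | lo
            continue
        t += delta + pending_skip
        pending_skip = 0
        anns.append(BeatAnnotation(t, _CODE_TO_SYMBOL.get(code, "?")))
    return anns


def read_record(path: str, leads: Optional[Sequence[str]] = None) -> AnnotatedRecord:
    """Read a WFDB record; `path` is the record base name (no extension).

    Only format-16 single-segment records are supported.  When `leads` is
    given, the signal is restricted to those leads in the requested order.
    """
    base = path[:-4] if path.endswith(".hea") else path
    hea = base + ".hea"
    if not os.path.exists(hea):
        raise FormatError(f"missing header file {hea}")
    with open(hea) as fh:
        lines = [
            ln.strip() for ln in fh
            if ln.strip() and not ln.startswith("#")
        ]
    try:
        head = lines[0].split()
        record_id, n_leads = head[0], int(head[1])
        fs = float(head[2]) if len(head) > 2 else 250.0
        n_samples = int(head[3]) if len(head) > 3 else 0
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed header line in {hea}") from exc
    if len(lines) < 1 + n_leads:
        raise FormatError(f"header {hea} declares {n_leads} leads, fewer given")

    lead_names, gains, dat_name = [], [], None
    for spec in lines[1 : 1 + n_leads]:
        parts = spec.split()
        if len(parts) < 2:
            raise FormatError(f"malformed signal line {spec!r}")
        dat_name = parts[0]
        if not parts[1].startswith("16"):
            raise FormatError(f"unsupported signal format {parts[1]!r}")
        gain = _ADC_GAIN
        if len(parts) > 2:
            gain = float(parts[2].split("(")[0].split("/")[0]) or _ADC_GAIN
        gains.append(gain)
        lead_names.append(parts[-1])
    dat_path = os.path.join(os.path.dirname(base) or ".", dat_name)
    if not os.path.exists(dat_path):
        raise FormatError(f"signal file {dat_path} referenced by header is missing")
    raw = np.fromfile(dat_path, dtype="<i2")
    if n_samples and raw.size < n_samples * n_leads:
        raise FormatError(
            f"signal file {dat_path} truncated: "
            f"{raw.size} < {n_samples * n_leads} samples"
        )
    raw = raw[: n_samples * n_leads] if n_samples else raw
    sig = raw.reshape(-1, n_leads).astype(float) / np.asarray(gains)

    annotations = []
    if os.path.exists(base + ".atr"):
        annotations = _read_annotations(base + ".atr")

    rec = AnnotatedRecord(record_id, fs, lead_names, sig, annotations)
    if leads is not None:
        idx = []
        for name in leads:
            if name not in lead_names:
                raise LeadNotFoundError(f"lead {name!r} not in {lead_names}")
            idx.append(lead_names.index(name))
        rec.signal = rec.signal[:, idx]
        rec.leads = list(leads)
    return rec


# --------------------------------------------------------------------------
# Segment dataset I/O (self-describing CSV)
# --------------------------------------------------------------------------

_SEG_MAGIC = "# cbgm-segments v1"


def write_segments(dataset: SegmentDataset, path: str) -> None:
    """Write a segment dataset as CSV with a metadata header."""
    n = Segment.SEGMENT_LENGTH
    cols = ["record_id", "r_index", "label"] + [f"v{i}" for i in range(n)]
    rows = [
        [s.record_id, s.r_index, s.label] + list(s.values)
        for s in dataset.segments
    ]
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(_SEG_MAGIC + f"\n# n_segments={len(dataset)} length={n}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_segments(path: str) -> SegmentDataset:
    """Read a segment dataset written by :func:`write_segments`."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_SEG_MAGIC):
            raise SchemaError(f"{path} is not a segment dataset file")
        try:
            df = pd.read_csv(fh, comment="#")
        except Exception as exc:
            raise SchemaError(f"cannot parse {path}: {exc}") from exc
    n = Segment.SEGMENT_LENGTH
    expected = 3 + n
    if df.shape[1] != expected:
        raise SchemaError(
            f"{path}: expected {expected} columns, found {df.shape[1]}"
        )
    if df.isna().any().any():
        raise SchemaError(f"{path}: truncated or non-numeric rows present")
    segments = [
        Segment(
            values=row[3:].to_numpy(dtype=float),
            label=str(row["label"]),
            r_index=int(row["r_index"]),
            record_id=str(row["record_id"]),
        )
        for _, row in df.iterrows()
    ]
    return SegmentDataset(segments)
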