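"""Minimal EDF (European Data Format, 16-bit) reader/writer.

Covers what continuous qEEG work needs: multi-channel signals with
per-channel physical calibration, 1 s data records, and a plain-text
annotation sidecar (``<file>.annotations.csv``) carrying labelled intervals.
Simulation bookkeeping (true sample count, time compression, start offset)
travels in the header's 44-byte reserved field so a write/read round trip
restores the recording exactly up to 16-bit quantization.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path

import numpy as np

from .recording import Annotation, EEGRecording

_HEADER_BYTES = 256
_SIGNAL_HEADER_BYTES = 256
_DIGITAL_MAX = 32767
_RESERVED_TAG = "NQG"


class EDFFormatError(ValueError):
    """Malformed EDF content; ``offset`` is the byte position of the fault."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (byte offset {offset})")
        self.offset = offset


def _field(text: str, width: int) -> bytes:
    raw = text.encode("ascii")
    if len(raw) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return raw.ljust(width)


def _fmt_float(value: float, width: int = 8) -> str:
    for spec in (".6g", ".5g", ".4g", ".3g", ".2g"):
        out = format(value, spec)
        if len(out) <= width:
            return out
    raise ValueError(f"cannot format {value} in {width} chars")


def write_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF plus an annotation sidecar CSV.

    Data records are one second long; a trailing partial record is
    zero-padded on disk and trimmed again on read via the reserved-field
    sample count.
    """
    path = Path(path)
    if recording.n_channels == 0:
        raise EDFFormatError("cannot write EDF with an empty channel list", 252)
    sfreq = recording.sampling_rate
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1 s record
    n_records = max(1, math.ceil(recording.n_samples / spr))

    reserved = (
        f"{_RESERVED_TAG} {recording.n_samples} "
        f"{recording.time_compression:g} {recording.start_offset_s:g}"
    )
    ns = recording.n_channels
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X neoqeeg synthetic", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(_HEADER_BYTES + ns * _SIGNAL_HEADER_BYTES), 8),
            _field(reserved, 44),
            _field(str(n_records), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )

    pmax = np.maximum(np.abs(recording.signal).max(axis=1, initial=0.0), 1.0)
    pmax = np.array([float(_fmt_float(v * 1.000001)) for v in pmax])
    scale = pmax / _DIGITAL_MAX

    sig_header = b"".join(
        [
            b"".join(_field(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_field("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(_field("uV", 8) for _ in range(ns)),
            b"".join(_field(_fmt_float(-p), 8) for p in pmax),
            b"".join(_field(_fmt_float(p), 8) for p in pmax),
            b"".join(_field(str(-_DIGITAL_MAX), 8) for _ in range(ns)),
            b"".join(_field(str(_DIGITAL_MAX), 8) for _ in range(ns)),
            b"".join(_field("", 80) for _ in range(ns)),
            b"".join(_field(str(spr), 8) for _ in range(ns)),
            b"".join(_field("", 32) for _ in range(ns)),
        ]
    )

    padded = np.zeros((ns, n_records * spr))
    padded[:, : recording.n_samples] = recording.signal
    digital = np.clip(
        np.round(padded / scale[:, None]), -_DIGITAL_MAX, _DIGITAL_MAX
    ).astype("<i2")
    # record-major interleaving: all samples of ch0 for record r, then ch1, ...
    blocks = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(blocks.tobytes())

    _write_annotation_sidecar(recording.annotations, _sidecar_path(path))
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".annotations.csv")


def _write_annotation_sidecar(annotations: list[Annotation], path: Path) -> None:
    if not annotations:
        path.unlink(missing_ok=True)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "start_s", "end_s", "channel_scope"])
        for a in annotations:
            writer.writerow([a.label, repr(float(a.start_s)), repr(float(a.end_s)), a.channel_scope])


def _read_annotation_sidecar(path: Path) -> list[Annotation]:
    if not path.exists():
        return []
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    return [
        Annotation(r["label"], float(r["start_s"]), float(r["end_s"]), r["channel_scope"])
        for r in rows
    ]


def _ascii(buf: bytes, start: int, width: int) -> str:
    return buf[start : start + width].decode("ascii", errors="replace").strip()


def _int_at(buf: bytes, start: int, width: int, what: str) -> int:
    text = _ascii(buf, start, width)
    try:
        return int(text)
    except ValueError:
        raise EDFFormatError(f"non-integer {what}: {text!r}", start) from None


def _float_at(buf: bytes, start: int, width: int, what: str) -> float:
    text = _ascii(buf, start, width)
    try:
        return float(text)
    except ValueError:
        raise EDFFormatError(f"non-numeric {what}: {text!r}", start) from None


def read_edf(path: str | Path) -> EEGRecording:
    """Read a 16-bit EDF file (and its annotation sidecar, if present)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_BYTES:
        raise EDFFormatError("file shorter than the 256-byte EDF header", len(raw))
    if _ascii(raw, 0, 8) != "0":
        raise EDFFormatError(f"unsupported EDF version field {_ascii(raw, 0, 8)!r}", 0)
    reserved = _ascii(raw, 192, 44)
    n_records = _int_at(raw, 236, 8, "number of data records")
    record_duration = _float_at(raw, 244, 8, "data record duration")
    ns = _int_at(raw, 252, 4, "number of signals")
    if ns <= 0:
        raise EDFFormatError("EDF file declares no signals", 252)
    hdr_end = _HEADER_BYTES + ns * _SIGNAL_HEADER_BYTES
    if len(raw) < hdr_end:
        raise EDFFormatError("truncated signal header block", len(raw))

    def col(offset: int, width: int) -> list[str]:
        base = _HEADER_BYTES + offset * ns
        return [_ascii(raw, base + i * width, width) for i in range(ns)]

    labels = col(0, 16)
    pmin = np.array([float(v) for v in col(104, 8)])
    pmax = np.array([float(v) for v in col(112, 8)])
    dmin = np.array([float(v) for v in col(120, 8)])
    dmax = np.array([float(v) for v in col(128, 8)])
    spr = np.array([int(v) for v in col(216, 8)])
    if len(set(spr)) != 1:
        raise EDFFormatError("mixed per-signal sampling rates are unsupported", _HEADER_BYTES)
    spr0 = int(spr[0])
    sfreq = spr0 / record_duration

    expected = n_records * ns * spr0 * 2
    data = np.frombuffer(raw, dtype="<i2", count=expected // 2, offset=hdr_end)
    if data.size * 2 < expected:
        raise EDFFormatError("data section shorter than header declares", hdr_end)
    digital = data.reshape(n_records, ns, spr0).transpose(1, 0, 2).reshape(ns, -1)
    gain = (pmax - pmin) / (dmax - dmin)
    physical = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]

    n_samples = n_records * spr0
    time_compression, start_offset = 1.0, 0.0
    if reserved.startswith(_RESERVED_TAG):
        parts = reserved.split()
        n_samples = min(int(parts[1]), n_samples)
        time_compression = float(parts[2])
        start_offset = float(parts[3])

    return EEGRecording(
        signal=physical[:, :n_samples],
        sampling_rate=sfreq,
        channel_labels=tuple(labels),
        start_offset_s=start_offset,
        annotations=_read_annotation_sidecar(_sidecar_path(path)),
        time_compression=time_compression,
    )
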