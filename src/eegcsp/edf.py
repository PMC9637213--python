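"""Minimal EDF / EDF+ reader producing :class:`~eegcsp.records.EEGRecord`.

Supports continuous (EDF / EDF+C) files with 16-bit samples, a common
sampling rate across EEG signals, and an optional ``EDF Annotations``
signal whose time-stamped annotations are mapped to task events through a
caller-supplied annotation->task mapping.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError
from .records import EEGRecord, Event

_ANNOTATION_LABEL = "EDF Annotations"


def _ascii(raw: bytes) -> str:
    return raw.decode("ascii", errors="replace").strip()


def _read_header(fh) -> dict:
    fixed = fh.read(256)
    if len(fixed) < 256:
        raise FormatError("truncated EDF header")
    header = {
        "version": _ascii(fixed[0:8]),
        "patient": _ascii(fixed[8:88]),
        "recording": _ascii(fixed[88:168]),
        "header_bytes": int(_ascii(fixed[184:192])),
        "reserved": _ascii(fixed[192:236]),
        "n_records": int(_ascii(fixed[236:244])),
        "record_duration": float(_ascii(fixed[244:252])),
        "n_signals": int(_ascii(fixed[252:256])),
    }
    ns = header["n_signals"]
    if ns <= 0:
        raise FormatError("EDF file declares no signals")

    def fields(width: int) -> list[str]:
        raw = fh.read(width * ns)
        if len(raw) < width * ns:
            raise FormatError("truncated EDF signal header")
        return [_ascii(raw[i * width : (i + 1) * width]) for i in range(ns)]

    header["labels"] = fields(16)
    fields(80)  # transducer
    header["phys_dim"] = fields(8)
    header["phys_min"] = [float(v) for v in fields(8)]
    header["phys_max"] = [float(v) for v in fields(8)]
    header["dig_min"] = [int(v) for v in fields(8)]
    header["dig_max"] = [int(v) for v in fields(8)]
    fields(80)  # prefilter
    header["samples_per_record"] = [int(v) for v in fields(8)]
    fields(32)  # reserved
    return header


def _parse_tals(raw: bytes) -> list[tuple[float, str]]:
    """(onset_seconds, text) pairs from an EDF+ annotation byte stream."""
    out: list[tuple[float, str]] = []
    for tal in raw.split(b"\x00"):
        if not tal:
            continue
        parts = tal.split(b"\x14")
        if not parts[0]:
            continue
        timestamp = parts[0].split(b"\x15")[0]
        try:
            onset = float(timestamp.decode("ascii"))
        except (UnicodeDecodeError, ValueError):
            continue
        for text in parts[1:]:
            if text:
                out.append((onset, text.decode("utf-8", errors="replace").strip()))
    return out


def read_edf(
    path: str | Path,
    annotation_map: dict[str, str] | None = None,
    subject_id: str | None = None,
    group: str = "unknown",
) -> EEGRecord:
    """Read a continuous EDF/EDF+ file.

    ``annotation_map`` maps annotation text to a task name; annotations not
    in the map are ignored. Annotation onsets are rounded to the nearest
    sample of the EEG sampling rate.
    """
    path = Path(path)
    with path.open("rb") as fh:
        header = _read_header(fh)
        ns = header["n_signals"]
        spr = header["samples_per_record"]
        is_annotation = [lbl == _ANNOTATION_LABEL for lbl in header["labels"]]
        eeg_idx = [i for i in range(ns) if not is_annotation[i]]
        if not eeg_idx:
            raise FormatError(f"{path}: no EEG signals")
        if header["record_duration"] <= 0:
            raise FormatError(f"{path}: non-positive data record duration")
        rates = {spr[i] / header["record_duration"] for i in eeg_idx}
        if len(rates) != 1:
            raise FormatError(f"{path}: EEG signals have mixed sampling rates")
        fs = rates.pop()

        n_records = header["n_records"]
        record_words = sum(spr)
        raw = np.fromfile(fh, dtype="<i2")
    if n_records < 0:  # unknown length: infer from file size
        n_records = raw.size // record_words
    if raw.size < n_records * record_words:
        raise FormatError(f"{path}: data area shorter than declared")
    raw = raw[: n_records * record_words].reshape(n_records, record_words)

    offsets = np.cumsum([0] + spr)
    channels: list[np.ndarray] = []
    labels: list[str] = []
    annotation_bytes = b""
    for i in range(ns):
        block = raw[:, offsets[i] : offsets[i + 1]]
        if is_annotation[i]:
            annotation_bytes += block.astype("<i2").tobytes()
            continue
        dmin, dmax = header["dig_min"][i], header["dig_max"][i]
        pmin, pmax = header["phys_min"][i], header["phys_max"][i]
        if dmax == dmin:
            raise FormatError(f"{path}: signal {i} has zero digital range")
        gain = (pmax - pmin) / (dmax - dmin)
        channels.append((block.ravel().astype(np.int64) - dmin) * gain + pmin)
        labels.append(header["labels"][i])

    events: list[Event] = []
    if annotation_map:
        for onset_s, text in _parse_tals(annotation_bytes):
            task = annotation_map.get(text)
            if task is not None:
                events.append(Event(task, int(round(onset_s * fs))))
        events.sort(key=lambda e: e.onset_sample)

    return EEGRecord(
        subject_id=subject_id or path.stem,
        group=group,
        channel_labels=tuple(labels),
        fs=fs,
        data=np.vstack(channels),
        events=events,
    )
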