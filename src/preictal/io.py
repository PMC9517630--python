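"""EDF record I/O and CHB-MIT-style summary annotation parsing.

The on-disk contract is the one the CHB-MIT scalp EEG corpus uses: plain
16-bit EDF signal files (physical dimension microvolts) plus a text summary
per patient listing each file's start/end clock time and the seizure
onset/offset seconds within each file.  Everything downstream works on an
absolute *patient timeline* in seconds, with time zero at the start of the
first file; gaps between consecutive files are materialized explicitly so
the segmentation stage can refuse to window across unrecorded stretches.

All intervals are half-open ``[start, end)`` seconds.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecord",
    "SeizureEvent",
    "RecordingGap",
    "FileSpan",
    "RecordingTimeline",
    "ChannelError",
    "SummaryParseError",
    "CHB_CHANNELS",
    "read_edf",
    "write_edf",
    "parse_summary",
    "serialize_summary",
]

#: Default 23-channel bipolar montage (10-20 longitudinal chains as used by
#: the CHB-MIT recordings; the corpus' duplicated T8-P8 lead is made unique).
CHB_CHANNELS = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
    "P7-T7", "T7-FT9", "FT9-FT10", "FT10-T8", "T8-P8-1",
]


class ChannelError(KeyError):
    """Requested channel label missing from an EDF file."""


class SummaryParseError(ValueError):
    """Malformed CHB-MIT summary text; carries a 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class EEGRecord:
    """Multichannel EEG signal in microvolts.

    ``start_time`` is the absolute offset (seconds) of the first sample on
    the patient timeline; ``data`` has shape (n_channels, n_samples).
    """

    channels: list[str]
    fs: int
    data: np.ndarray
    start_time: float = 0.0
    file_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be (n_channels, n_samples) matching channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] < 1:
            raise ValueError("record must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SeizureEvent:
    """One annotated seizure, with onset/offset in seconds from file start."""

    file_id: str
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.onset_s < self.offset_s):
            raise ValueError("require 0 <= onset_s < offset_s")


@dataclass(frozen=True)
class RecordingGap:
    """Unrecorded stretch of the patient timeline between two files."""

    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.start_s > self.end_s:
            raise ValueError("gap start after end")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class FileSpan:
    """Placement of one EDF file on the absolute patient timeline."""

    file_id: str
    start_abs_s: float
    end_abs_s: float

    def __post_init__(self) -> None:
        if self.start_abs_s >= self.end_abs_s:
            raise ValueError("file span must have positive duration")


@dataclass
class RecordingTimeline:
    """Parsed summary: file placements, seizures and reconstructed gaps."""

    fs: int
    files: list[FileSpan] = field(default_factory=list)
    events: list[SeizureEvent] = field(default_factory=list)
    gaps: list[RecordingGap] = field(default_factory=list)

    @property
    def start_s(self) -> float:
        return self.files[0].start_abs_s if self.files else 0.0

    @property
    def end_s(self) -> float:
        return self.files[-1].end_abs_s if self.files else 0.0

    def file_start(self, file_id: str) -> float:
        for fsp in self.files:
            if fsp.file_id == file_id:
                return fsp.start_abs_s
        raise KeyError(file_id)

    def event_abs_interval(self, ev: SeizureEvent) -> tuple[float, float]:
        """Seizure interval on the absolute patient timeline."""
        t0 = self.file_start(ev.file_id)
        return (t0 + ev.onset_s, t0 + ev.offset_s)

    def seizure_intervals(self) -> list[tuple[float, float]]:
        return sorted(self.event_abs_interval(ev) for ev in self.events)

    def is_recorded(self, t0: float, t1: float) -> bool:
        """True iff [t0, t1) lies inside the recording and crosses no gap."""
        if not self.files or t0 < self.start_s or t1 > self.end_s:
            return False
        for gap in self.gaps:
            if gap.duration_s > 0 and t0 < gap.end_s and gap.start_s < t1:
                return False
        return True

    def files_overlapping(self, t0: float, t1: float) -> list[FileSpan]:
        return [f for f in self.files if f.start_abs_s < t1 and t0 < f.end_abs_s]


# ---------------------------------------------------------------------------
# EDF writing (plain EDF, 16-bit, 1-second data records)
# ---------------------------------------------------------------------------

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, record: EEGRecord, *, patient_id: str = "X",
              recording_id: str = "synthetic") -> None:
    """Write a plain 16-bit EDF file (physical dimension uV).

    The record length must be a whole number of seconds; each data record
    holds one second of samples per signal.  Per-signal physical ranges are
    symmetric around zero and sized to the channel's absolute maximum, so
    the worst-case round-trip error is one quantization step
    ``(phys_max - phys_min) / (dig_max - dig_min)``.
    """
    if record.n_samples % record.fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds")
    n_records = record.n_samples // record.fs
    ns = len(record.channels)

    phys_max = np.maximum(np.max(np.abs(record.data), axis=1), 1.0)
    phys_min = -phys_max

    start = int(record.start_time) % 86400
    hh, rem = divmod(start, 3600)
    mm, ss = divmod(rem, 60)

    header = b"".join([
        _pad("0", 8),
        _pad(patient_id, 80),
        _pad(recording_id, 80),
        _pad("01.01.00", 8),
        _pad(f"{hh:02d}.{mm:02d}.{ss:02d}", 8),
        _pad(str(256 * (ns + 1)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    header += b"".join(_pad(ch, 16) for ch in record.channels)
    header += b"".join(_pad("", 80) for _ in range(ns))          # transducer
    header += b"".join(_pad("uV", 8) for _ in range(ns))
    header += b"".join(_pad(f"{v:.6g}", 8) for v in phys_min)
    header += b"".join(_pad(f"{v:.6g}", 8) for v in phys_max)
    header += b"".join(_pad(str(_DIG_MIN), 8) for _ in range(ns))
    header += b"".join(_pad(str(_DIG_MAX), 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))          # prefiltering
    header += b"".join(_pad(str(record.fs), 8) for _ in range(ns))
    header += b"".join(_pad("", 32) for _ in range(ns))          # reserved

    scale = (_DIG_MAX - _DIG_MIN) / (2.0 * phys_max)
    digital = np.rint((record.data - phys_min[:, None]) * scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    # (ns, n_records, fs) -> records-major layout on disk
    blocks = digital.reshape(ns, n_records, record.fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def quantization_step(data: np.ndarray) -> np.ndarray:
    """Per-channel physical size of one 16-bit digital step for `write_edf`."""
    phys_max = np.maximum(np.max(np.abs(data), axis=1), 1.0)
    return 2.0 * phys_max / (_DIG_MAX - _DIG_MIN)


def _edf_header_labels(path: str | Path) -> list[str]:
    with open(path, "rb") as fh:
        head = fh.read(256)
        ns = int(head[252:256].decode("ascii").strip())
        raw = fh.read(16 * ns)
    return [raw[i * 16:(i + 1) * 16].decode("ascii").strip() for i in range(ns)]


def read_edf(path: str | Path, channel_subset: list[str] | None = None,
             start_time: float = 0.0) -> EEGRecord:
    """Read an EDF file into an :class:`EEGRecord` (microvolts).

    Duplicate channel labels keep the first occurrence with a warning.
    ``channel_subset`` selects and orders channels; an unknown label raises
    :class:`ChannelError`, an empty list is rejected.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if channel_subset is not None and len(channel_subset) == 0:
        raise ChannelError("empty channel selection")

    labels = _edf_header_labels(path)
    keep_idx: list[int] = []
    seen: set[str] = set()
    for i, lab in enumerate(labels):
        if lab in seen:
            warnings.warn(f"duplicate channel label {lab!r} in {path.name}; "
                          "keeping first occurrence")
            continue
        seen.add(lab)
        keep_idx.append(i)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data_uv = raw.get_data(units="uV")
    fs = int(round(raw.info["sfreq"]))

    channels = [labels[i] for i in keep_idx]
    data = data_uv[keep_idx]

    if channel_subset is not None:
        pos = {ch: i for i, ch in enumerate(channels)}
        missing = [ch for ch in channel_subset if ch not in pos]
        if missing:
            raise ChannelError(f"channel(s) not in {path.name}: {missing}")
        order = [pos[ch] for ch in channel_subset]
        channels = list(channel_subset)
        data = data[order]

    return EEGRecord(channels=channels, fs=fs, data=data,
                     start_time=start_time, file_id=path.name)


# ---------------------------------------------------------------------------
# Summary annotation text
# ---------------------------------------------------------------------------

_RE_FS = re.compile(r"Data Sampling Rate:\s*(\d+)\s*Hz", re.I)
_RE_FILE = re.compile(r"File Name:\s*(\S+)", re.I)
_RE_START = re.compile(r"File Start Time:\s*(\d+):(\d{1,2}):(\d{1,2})", re.I)
_RE_END = re.compile(r"File End Time:\s*(\d+):(\d{1,2}):(\d{1,2})", re.I)
_RE_NSEIZ = re.compile(r"Number of Seizures in File:\s*(\d+)", re.I)
# tolerate both corpus dialects: "Seizure Start Time" and "Seizure 1 Start Time"
_RE_SSTART = re.compile(r"Seizure\s*(?:\d+\s*)?Start Time:\s*([\d.]+)\s*sec", re.I)
_RE_SEND = re.compile(r"Seizure\s*(?:\d+\s*)?End Time:\s*([\d.]+)\s*sec", re.I)


def _clock_s(h: int, m: int, s: int) -> float:
    return 3600.0 * h + 60.0 * m + s


def parse_summary(text: str) -> RecordingTimeline:
    """Parse CHB-MIT-style summary text into a :class:`RecordingTimeline`.

    File clock times are unwrapped across midnight (a start time smaller
    than the previous file's is advanced by 24 h) and shifted so the first
    file begins at patient-timeline second 0.  Gaps between consecutive
    files are reconstructed from the start/end times; negative overlaps are
    a parse error.
    """
    fs = 256
    blocks: list[dict] = []
    current: dict | None = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        m = _RE_FS.search(line)
        if m:
            fs = int(m.group(1))
            continue
        m = _RE_FILE.search(line)
        if m:
            current = {"file_id": m.group(1), "line": lineno, "starts": [], "ends": []}
            blocks.append(current)
            continue
        if current is None:
            continue
        m = _RE_START.search(line)
        if m:
            current["start_clock"] = _clock_s(*(int(g) for g in m.groups()))
            continue
        m = _RE_END.search(line)
        if m:
            current["end_clock"] = _clock_s(*(int(g) for g in m.groups()))
            continue
        m = _RE_NSEIZ.search(line)
        if m:
            current["n_seizures"] = int(m.group(1))
            current["nseiz_line"] = lineno
            continue
        m = _RE_SSTART.search(line)
        if m:
            current["starts"].append(float(m.group(1)))
            continue
        m = _RE_SEND.search(line)
        if m:
            current["ends"].append(float(m.group(1)))
            continue

    files: list[FileSpan] = []
    events: list[SeizureEvent] = []
    gaps: list[RecordingGap] = []
    unwrap = 0.0
    prev_clock = None
    origin = None
    prev_end = None

    for blk in blocks:
        for key in ("start_clock", "end_clock"):
            if key not in blk:
                raise SummaryParseError(
                    f"file block {blk['file_id']} missing {key.replace('_', ' ')}",
                    blk["line"])
        n_declared = blk.get("n_seizures", len(blk["starts"]))
        if n_declared != len(blk["starts"]) or n_declared != len(blk["ends"]):
            raise SummaryParseError(
                f"{blk['file_id']}: declared {n_declared} seizure(s) but found "
                f"{len(blk['starts'])} start / {len(blk['ends'])} end time(s)",
                blk.get("nseiz_line", blk["line"]))

        start = blk["start_clock"] + unwrap
        if prev_clock is not None and start < prev_clock:
            unwrap += 86400.0
            start += 86400.0
        end = blk["end_clock"] + unwrap
        if end < start:
            end += 86400.0
            unwrap += 86400.0
        prev_clock = start
        if origin is None:
            origin = start
        start_abs, end_abs = start - origin, end - origin

        if prev_end is not None:
            if start_abs < prev_end - 1e-9:
                raise SummaryParseError(
                    f"{blk['file_id']} starts before previous file ends", blk["line"])
            if start_abs > prev_end:
                gaps.append(RecordingGap(prev_end, start_abs))
        prev_end = end_abs

        files.append(FileSpan(blk["file_id"], start_abs, end_abs))
        for s, e in zip(blk["starts"], blk["ends"]):
            events.append(SeizureEvent(blk["file_id"], s, e))

    order = {f.file_id: i for i, f in enumerate(files)}
    events.sort(key=lambda ev: (order[ev.file_id], ev.onset_s))
    return RecordingTimeline(fs=fs, files=files, events=events, gaps=gaps)


def _fmt_clock(t: float) -> str:
    t = int(round(t))
    h, rem = divmod(t, 3600)
    m, s = divmod(rem, 60)
    return f"{h}:{m:02d}:{s:02d}"


def serialize_summary(timeline: RecordingTimeline) -> str:
    """Render a timeline back to CHB-MIT summary text.

    Single-seizure files use the unnumbered dialect ("Seizure Start Time"),
    multi-seizure files the numbered one, so both corpus variants stay
    exercised by the round trip.
    """
    lines = [f"Data Sampling Rate: {timeline.fs} Hz",
             "*************************", ""]
    by_file: dict[str, list[SeizureEvent]] = {f.file_id: [] for f in timeline.files}
    for ev in timeline.events:
        by_file[ev.file_id].append(ev)

    for fsp in timeline.files:
        evs = sorted(by_file[fsp.file_id], key=lambda e: e.onset_s)
        lines.append(f"File Name: {fsp.file_id}")
        lines.append(f"File Start Time: {_fmt_clock(fsp.start_abs_s)}")
        lines.append(f"File End Time: {_fmt_clock(fsp.end_abs_s)}")
        lines.append(f"Number of Seizures in File: {len(evs)}")
        for i, ev in enumerate(evs, start=1):
            tag = "" if len(evs) == 1 else f" {i}"
            lines.append(f"Seizure{tag} Start Time: {ev.onset_s:g} seconds")
            lines.append(f"Seizure{tag} End Time: {ev.offset_s:g} seconds")
        lines.append("")
    return "\n".join(lines)
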