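"""Pre-seizure / seizure-free epoch selection and windowing.

Two classes of 10-min epochs are cut from the patient timeline:

* **category A** (label 1): the 10 minutes ending ``InT`` minutes before an
  eligible seizure onset, i.e. ``[onset - (InT + 10) min, onset - InT min)``.
  A seizure is eligible only if no other seizure (onset *or* offset) falls
  in the ``isolation_hours`` before it and its A interval is fully recorded
  (no inter-file gap).
* **category B** (label 0): 10-min blocks drawn uniformly at random (seeded)
  from the first ``b_pick_hours`` of distinct, disjoint seizure-free spans
  of ``b_search_hours``, so that by construction no seizure follows a B
  block within InT + 10 min.  One block per span; blocks never overlap.

Each epoch is then partitioned into consecutive non-overlapping analysis
windows of ``window_s`` seconds (60 windows at the defaults).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import RecordingTimeline, SeizureEvent

__all__ = ["SegmentSpec", "Segment", "ShortageError", "EDFDirectorySource",
           "select_seizures", "extract_category_a", "extract_category_b",
           "window_segment", "load_segment_data", "build_segments",
           "segment_manifest"]


@dataclass(frozen=True)
class SegmentSpec:
    """Epoch-selection parameters (times in the units their names state)."""

    int_minutes: float = 30.0
    pre_window_minutes: float = 10.0
    isolation_hours: float = 2.0
    b_search_hours: float = 4.0
    b_pick_hours: float = 3.0
    window_s: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("int_minutes", "pre_window_minutes", "isolation_hours",
                     "b_search_hours", "b_pick_hours", "window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pre_window_minutes * 60 > self.b_pick_hours * 3600:
            raise ValueError("pre window must fit inside the B pick span")

    @property
    def pre_window_s(self) -> float:
        return self.pre_window_minutes * 60.0

    def a_interval(self, onset_abs_s: float) -> tuple[float, float]:
        hi = onset_abs_s - self.int_minutes * 60.0
        return (hi - self.pre_window_s, hi)


@dataclass
class Segment:
    """One labeled 10-min epoch; ``windows`` filled by :func:`window_segment`."""

    label: int
    start_abs_s: float
    end_abs_s: float
    source_seizure: SeizureEvent | None = None
    source_files: list[str] = field(default_factory=list)
    data: np.ndarray | None = None       # (n_channels, n_samples)
    windows: np.ndarray | None = None    # (n_windows, n_channels, win_samples)

    @property
    def duration_s(self) -> float:
        return self.end_abs_s - self.start_abs_s


class ShortageError(RuntimeError):
    """Fewer qualifying interictal spans than requested B segments."""

    def __init__(self, requested: int, found: int):
        super().__init__(f"requested {requested} interictal spans, found {found}")
        self.requested = requested
        self.found = found


def select_seizures(events: list[SeizureEvent], timeline: RecordingTimeline,
                    spec: SegmentSpec) -> list[SeizureEvent]:
    """Eligible seizures: isolated and with a fully recorded A interval."""
    iso = spec.isolation_hours * 3600.0
    intervals = {ev: timeline.event_abs_interval(ev) for ev in events}
    out = []
    for ev in sorted(events, key=lambda e: intervals[e][0]):
        onset, _ = intervals[ev]
        clean = True
        for other in events:
            if other is ev:
                continue
            o_on, o_off = intervals[other]
            # any ictal activity inside [onset - iso, onset) disqualifies
            if o_on < onset and o_off > onset - iso:
                clean = False
                break
        if not clean:
            continue
        a0, a1 = spec.a_interval(onset)
        if timeline.is_recorded(a0, a1):
            out.append(ev)
    return out


def extract_category_a(timeline: RecordingTimeline,
                       eligible: list[SeizureEvent],
                       spec: SegmentSpec) -> list[Segment]:
    """One label-1 segment per eligible seizure (no sample data yet)."""
    segments = []
    for ev in eligible:
        onset, _ = timeline.event_abs_interval(ev)
        a0, a1 = spec.a_interval(onset)
        if a0 < timeline.start_s or not timeline.is_recorded(a0, a1):
            warnings.warn(f"dropping seizure at {onset:.0f} s: pre-seizure "
                          "interval not fully recorded")
            continue
        files = [f.file_id for f in timeline.files_overlapping(a0, a1)]
        segments.append(Segment(label=1, start_abs_s=a0, end_abs_s=a1,
                                source_seizure=ev, source_files=files))
    return segments


def _seizure_free_intervals(timeline: RecordingTimeline) -> list[tuple[float, float]]:
    bounds = [(timeline.start_s, timeline.end_s)]
    for s0, s1 in timeline.seizure_intervals():
        nxt = []
        for a, b in bounds:
            if s1 <= a or s0 >= b:
                nxt.append((a, b))
            else:
                if a < s0:
                    nxt.append((a, s0))
                if s1 < b:
                    nxt.append((s1, b))
        bounds = nxt
    return bounds


def extract_category_b(timeline: RecordingTimeline, events: list[SeizureEvent],
                       n: int, spec: SegmentSpec) -> list[Segment]:
    """``n`` label-0 segments, one per disjoint seizure-free span (seeded)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    span_len = spec.b_search_hours * 3600.0
    pick_len = spec.b_pick_hours * 3600.0
    blk = spec.pre_window_s

    spans: list[tuple[float, float]] = []
    for a, b in _seizure_free_intervals(timeline):
        t = a
        while t + span_len <= b:
            spans.append((t, t + span_len))
            t += span_len
    if len(spans) < n:
        raise ShortageError(n, len(spans))

    rng = np.random.default_rng(spec.rng_seed)
    seiz = timeline.seizure_intervals()
    guard = (spec.int_minutes + spec.pre_window_minutes) * 60.0
    segments = []
    for span_start, span_end in spans[:n]:
        hi = int(min(pick_len, span_end - span_start) - blk)
        t0 = None
        for _ in range(500):
            cand = span_start + float(rng.integers(0, hi + 1))
            if timeline.is_recorded(cand, cand + blk):
                t0 = cand
                break
        if t0 is None:  # deterministic sweep fallback for gap-riddled spans
            for off in range(0, hi + 1, 10):
                cand = span_start + off
                if timeline.is_recorded(cand, cand + blk):
                    t0 = cand
                    break
        if t0 is None:
            raise ShortageError(n, len(segments))
        assert all(not (t0 <= s0 < t0 + blk + guard) for s0, _ in seiz), \
            "interictal block followed too closely by a seizure"
        files = [f.file_id for f in timeline.files_overlapping(t0, t0 + blk)]
        segments.append(Segment(label=0, start_abs_s=t0, end_abs_s=t0 + blk,
                                source_files=files))
    return segments


def window_segment(segment: Segment, fs: int, spec: SegmentSpec) -> Segment:
    """Partition a loaded segment into consecutive ``window_s`` windows."""
    if segment.data is None:
        raise ValueError("segment has no sample data; load it first")
    n_ch, n_samp = segment.data.shape
    wlen = int(round(spec.window_s * fs))
    if n_samp % wlen != 0:
        raise ValueError(f"segment length {n_samp} samples is not divisible "
                         f"by the {wlen}-sample window")
    n_win = n_samp // wlen
    windows = segment.data.reshape(n_ch, n_win, wlen).transpose(1, 0, 2).copy()
    return replace_windows(segment, windows)


def replace_windows(segment: Segment, windows: np.ndarray) -> Segment:
    seg = replace(segment)
    seg.data = segment.data
    seg.windows = windows
    return seg


class EDFDirectorySource:
    """Lazy sample access over a directory of EDF files on a timeline.

    Files are opened on demand (``mne`` without preload) and only the
    requested sample ranges are pulled from disk; cross-file requests are
    concatenated, and any request touching a gap fails.
    """

    def __init__(self, directory: str | Path, timeline: RecordingTimeline,
                 channels: list[str] | None = None):
        self.directory = Path(directory)
        self.timeline = timeline
        self.channels = channels
        self._cache: dict[str, object] = {}

    def _raw(self, file_id: str):
        if file_id not in self._cache:
            import mne
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._cache[file_id] = mne.io.read_raw_edf(
                    self.directory / file_id, preload=False, verbose="error")
        return self._cache[file_id]

    def get(self, t0: float, t1: float) -> np.ndarray:
        """Samples for [t0, t1) as (n_channels, n_samples) in microvolts."""
        if not self.timeline.is_recorded(t0, t1):
            raise ValueError(f"[{t0}, {t1}) is not fully recorded")
        chunks = []
        for fsp in self.timeline.files_overlapping(t0, t1):
            raw = self._raw(fsp.file_id)
            fs = int(round(raw.info["sfreq"]))
            a = max(t0, fsp.start_abs_s)
            b = min(t1, fsp.end_abs_s)
            i0 = int(round((a - fsp.start_abs_s) * fs))
            i1 = int(round((b - fsp.start_abs_s) * fs))
            data = raw.get_data(start=i0, stop=i1, units="uV")
            if self.channels is not None:
                names = raw.ch_names
                idx = [names.index(ch) for ch in self.channels]
                data = data[idx]
            chunks.append(data)
        return np.concatenate(chunks, axis=1)


def load_segment_data(segment: Segment, source: EDFDirectorySource) -> Segment:
    seg = replace(segment)
    seg.data = source.get(segment.start_abs_s, segment.end_abs_s)
    return seg


def build_segments(timeline: RecordingTimeline, source: EDFDirectorySource,
                   spec: SegmentSpec, fs: int | None = None) -> list[Segment]:
    """Full selection stage: balanced, windowed A and B segments."""
    fs = fs or timeline.fs
    eligible = select_seizures(timeline.events, timeline, spec)
    a_segments = extract_category_a(timeline, eligible, spec)
    b_segments = extract_category_b(timeline, timeline.events,
                                    len(a_segments), spec)
    out = []
    for seg in a_segments + b_segments:
        out.append(window_segment(load_segment_data(seg, source), fs, spec))
    return out


def segment_manifest(segments: list[Segment]) -> pd.DataFrame:
    """Tabular manifest (written as CSV by the CLI)."""
    return pd.DataFrame({
        "label": [s.label for s in segments],
        "start_abs_s": [s.start_abs_s for s in segments],
        "end_abs_s": [s.end_abs_s for s in segments],
        "source_files": [";".join(s.source_files) for s in segments],
    })
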