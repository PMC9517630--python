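"""Synthetic multichannel scalp-EEG generator with ground-truth annotations.

The generator emulates the statistical structure the prediction pipeline
assumes about a long-term scalp recording, without claiming physiological
seizure morphology:

* baseline activity is pink (power ~ 1/f) noise per channel, with a shared
  low-rank component for inter-channel correlation;
* in the pre-seizure stretch ``[onset - (InT + 10) min, onset)`` the
  dynamics shift toward lower complexity — an amplitude-modulated 3-7 Hz
  oscillation is mixed in with weight ``class_effect`` (0 = no shift);
* optional >30 Hz artifact bursts emulate EMG contamination;
* the recording is split into fixed-length EDF files separated by short
  unrecorded gaps, and a CHB-MIT-dialect summary file carries the seizure
  annotations, exactly as the I/O layer expects.

All randomness descends from one root seed through
``numpy.random.SeedSequence(seed, spawn_key=(file_index, stream))`` where
stream 0..n_channels-1 are the per-channel noises, stream 1000 the shared
component and stream 1001 the artifact schedule, so records are bit-identical
for a given spec.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import (CHB_CHANNELS, EEGRecord, FileSpan, RecordingGap,
                 RecordingTimeline, SeizureEvent, serialize_summary, write_edf)

__all__ = ["SynthSpec", "SynthRecord", "generate_record", "generate_benchmark",
           "benchmark_spec"]


@dataclass
class SynthSpec:
    """Conditions for one synthetic patient recording."""

    seed: int = 0
    n_channels: int = 23
    fs: int = 256
    n_files: int = 3
    file_length_s: int = 3600
    gap_s: float = 10.0                      # between consecutive files
    gap_schedule: list[float] | None = None  # overrides gap_s per boundary
    seizure_times: list[float] = field(default_factory=list)  # absolute onsets, s
    seizure_duration_s: float = 60.0
    int_minutes: float = 30.0                # InT painted before each onset
    class_effect: float = 1.0                # pre-seizure complexity shift weight
    artifact_rate: float = 0.5               # >30 Hz bursts per minute
    amplitude_uv: float = 50.0               # baseline std in microvolts
    common_weight: float = 0.3               # shared-component mixing weight
    osc_freq_range: tuple[float, float] = (3.0, 7.0)
    file_prefix: str = "synth"
    channels: list[str] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.n_channels <= 0 or self.n_files <= 0:
            raise ValueError("fs, n_channels and n_files must be positive")
        if self.class_effect < 0:
            raise ValueError("class_effect must be >= 0")
        if self.channels is None:
            if self.n_channels <= len(CHB_CHANNELS):
                self.channels = CHB_CHANNELS[: self.n_channels]
            else:
                self.channels = CHB_CHANNELS + [
                    f"CH{i}" for i in range(len(CHB_CHANNELS), self.n_channels)]
        if self.gap_schedule is None:
            self.gap_schedule = [self.gap_s] * (self.n_files - 1)
        if len(self.gap_schedule) != self.n_files - 1:
            raise ValueError("gap_schedule needs n_files - 1 entries")
        pre_s = (self.int_minutes + 10.0) * 60.0
        for t in self.seizure_times:
            if t - pre_s < 0:
                raise ValueError(
                    f"seizure at {t} s too early for a full pre-seizure interval")
            if t + self.seizure_duration_s > self.total_span_s:
                raise ValueError(f"seizure at {t} s beyond the recording")

    @property
    def file_starts(self) -> list[float]:
        starts, t = [], 0.0
        for i in range(self.n_files):
            starts.append(t)
            t += self.file_length_s
            if i < self.n_files - 1:
                t += self.gap_schedule[i]
        return starts

    @property
    def total_span_s(self) -> float:
        return self.file_starts[-1] + self.file_length_s


@dataclass
class SynthRecord:
    """In-memory generation result: one EEGRecord per file + annotations."""

    records: list[EEGRecord]
    timeline: RecordingTimeline
    summary: str
    manifest: dict


def _pink(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance pink noise (power density ~ 1/f) via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    spec[0] = 0.0
    spec[1:] /= np.sqrt(f[1:] / f[1])
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _rng(spec: SynthSpec, file_index: int, stream: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(file_index, stream))
    return np.random.default_rng(ss)


def _quantize(x: np.ndarray) -> np.ndarray:
    """Emulate 16-bit acquisition over a symmetric per-channel range."""
    phys_max = np.maximum(np.max(np.abs(x), axis=1, keepdims=True), 1.0)
    step = 2.0 * phys_max / 65535.0
    return np.rint(x / step) * step


def _gen_file(spec: SynthSpec, file_index: int, file_start: float) -> np.ndarray:
    n = spec.file_length_s * spec.fs
    t_abs = file_start + np.arange(n) / spec.fs

    common = _pink(_rng(spec, file_index, 1000), n)
    w = spec.common_weight
    norm = math.sqrt(1.0 + w * w)

    data = np.empty((spec.n_channels, n))
    for c in range(spec.n_channels):
        data[c] = (_pink(_rng(spec, file_index, c), n) + w * common) / norm

    # pre-seizure low-complexity mixing and crude ictal rhythm
    pre_s = (spec.int_minutes + 10.0) * 60.0
    e = spec.class_effect
    for k, onset in enumerate(spec.seizure_times):
        rng_s = _rng(spec, 0, 2000 + k)
        f_osc = rng_s.uniform(*spec.osc_freq_range)
        f_am = rng_s.uniform(0.05, 0.3)
        phases = rng_s.uniform(0, 2 * np.pi, size=spec.n_channels)
        am_phase = rng_s.uniform(0, 2 * np.pi)

        if e > 0:
            mask = (t_abs >= onset - pre_s) & (t_abs < onset)
            if mask.any():
                tt = t_abs[mask]
                am = 1.0 + 0.8 * np.sin(2 * np.pi * f_am * tt + am_phase)
                for c in range(spec.n_channels):
                    osc = math.sqrt(2.0) * np.sin(
                        2 * np.pi * f_osc * tt + phases[c]) * am / 1.25
                    data[c, mask] = (data[c, mask] + e * osc) / math.sqrt(1 + e * e)

        ict = (t_abs >= onset) & (t_abs < onset + spec.seizure_duration_s)
        if ict.any():
            tt = t_abs[ict]
            for c in range(spec.n_channels):
                data[c, ict] += 3.0 * np.sin(2 * np.pi * 3.0 * tt + phases[c])

    # >30 Hz bursts (EMG-like), Poisson-scheduled per file
    if spec.artifact_rate > 0:
        rng_a = _rng(spec, file_index, 1001)
        n_bursts = rng_a.poisson(spec.artifact_rate * spec.file_length_s / 60.0)
        for _ in range(n_bursts):
            t0 = rng_a.uniform(0, spec.file_length_s - 0.5)
            f_b = rng_a.uniform(35.0, 60.0)
            i0 = int(t0 * spec.fs)
            L = int(0.5 * spec.fs)
            env = np.hanning(L)
            burst = 2.0 * env * np.sin(2 * np.pi * f_b * np.arange(L) / spec.fs)
            chans = rng_a.choice(spec.n_channels,
                                 size=max(1, spec.n_channels // 3), replace=False)
            data[np.ix_(chans, range(i0, i0 + L))] += burst

    return _quantize(spec.amplitude_uv * data)


def _timeline(spec: SynthSpec) -> RecordingTimeline:
    starts = spec.file_starts
    files, gaps, events = [], [], []
    for i, s in enumerate(starts):
        fid = f"{spec.file_prefix}_{i:02d}.edf"
        files.append(FileSpan(fid, s, s + spec.file_length_s))
        if i < spec.n_files - 1 and spec.gap_schedule[i] > 0:
            gaps.append(RecordingGap(s + spec.file_length_s,
                                     starts[i + 1]))
    for onset in spec.seizure_times:
        for fsp in files:
            if fsp.start_abs_s <= onset < fsp.end_abs_s:
                events.append(SeizureEvent(
                    fsp.file_id, onset - fsp.start_abs_s,
                    min(onset + spec.seizure_duration_s, fsp.end_abs_s)
                    - fsp.start_abs_s))
                break
        else:
            raise ValueError(f"seizure onset {onset} s falls in a gap")
    return RecordingTimeline(fs=spec.fs, files=files, events=events, gaps=gaps)


def _manifest(spec: SynthSpec, timeline: RecordingTimeline) -> dict:
    return {
        "seed": spec.seed,
        "fs": spec.fs,
        "n_channels": spec.n_channels,
        "channels": spec.channels,
        "class_effect": spec.class_effect,
        "int_minutes": spec.int_minutes,
        "files": [asdict(f) for f in timeline.files],
        "gaps": [asdict(g) for g in timeline.gaps],
        "seizures_abs": [
            {"onset_abs_s": t, "offset_abs_s": t + spec.seizure_duration_s}
            for t in spec.seizure_times],
        "effect_intervals": [
            [t - (spec.int_minutes + 10.0) * 60.0, t] for t in spec.seizure_times],
    }


def generate_record(spec: SynthSpec) -> SynthRecord:
    """Generate the full recording in memory (one EEGRecord per file)."""
    timeline = _timeline(spec)
    records = []
    for i, fsp in enumerate(timeline.files):
        data = _gen_file(spec, i, fsp.start_abs_s)
        records.append(EEGRecord(channels=list(spec.channels), fs=spec.fs,
                                 data=data, start_time=fsp.start_abs_s,
                                 file_id=fsp.file_id))
    return SynthRecord(records=records, timeline=timeline,
                       summary=serialize_summary(timeline),
                       manifest=_manifest(spec, timeline))


def generate_benchmark(out_dir: str | Path, spec: SynthSpec) -> dict:
    """Write a ready-to-run patient directory (EDF set + summary + manifest).

    Files are generated and written one at a time so memory stays bounded
    for day-scale records.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timeline = _timeline(spec)
    for i, fsp in enumerate(timeline.files):
        data = _gen_file(spec, i, fsp.start_abs_s)
        rec = EEGRecord(channels=list(spec.channels), fs=spec.fs, data=data,
                        start_time=fsp.start_abs_s, file_id=fsp.file_id)
        write_edf(out / fsp.file_id, rec)
    (out / f"{spec.file_prefix}-summary.txt").write_text(
        serialize_summary(timeline))
    manifest = _manifest(spec, timeline)
    manifest["out_dir"] = str(out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def benchmark_spec(seed: int = 0, n_seizures: int = 4, int_minutes: float = 30.0,
                   n_channels: int = 23, class_effect: float = 1.0,
                   fs: int = 256, file_length_s: int = 3600,
                   **overrides) -> SynthSpec:
    """Default patient layout sized so the segmentation stage finds exactly
    ``n_seizures`` eligible seizures and as many interictal candidates.

    Seizures sit in every other file starting at file 3, staggered a few
    minutes apart so consecutive onsets are > 2 h + seizure duration apart
    (the isolation rule holds even against the previous seizure's offset)
    and the 10-min pre-seizure extraction interval never crosses a file
    boundary for InT of 30 or 40 min.  After the last seizure the recording
    continues for a little over ``4 * n_seizures`` hours of seizure-free
    data, enough for the interictal span search.
    """
    if n_seizures < 1:
        raise ValueError("n_seizures >= 1")
    scale = file_length_s / 3600.0
    seizure_files = [3 + 2 * k for k in range(n_seizures)]
    n_files = seizure_files[-1] + 1 + int(math.ceil(4 * n_seizures / scale)) + 1
    gap_s = overrides.pop("gap_s", 10.0)
    starts = []
    t = 0.0
    for i in range(n_files):
        starts.append(t)
        t += file_length_s + gap_s
    seizure_times = [starts[fidx] + (3000.0 + 180.0 * k) * scale
                     for k, fidx in enumerate(seizure_files)]
    return SynthSpec(seed=seed, n_channels=n_channels, fs=fs, n_files=n_files,
                     file_length_s=file_length_s, gap_s=gap_s,
                     seizure_times=seizure_times, int_minutes=int_minutes,
                     class_effect=class_effect, **overrides)
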