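"""Shared fixtures: synthetic patients at two scales.

The *benchmark* fixtures reproduce the canonical study layout (23 channels,
256 Hz, 4 eligible seizures -> 480 windows x 116 feature columns) and are
session-scoped because generating and featurizing a day-long 23-channel
record takes minutes.  The *small* fixtures (1 seizure, 2-4 channels) cover
the same code paths cheaply for unit tests.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pytest

from preictal.entropy import build_feature_matrix
from preictal.io import parse_summary
from preictal.segmentation import EDFDirectorySource, SegmentSpec, build_segments
from preictal.synth import benchmark_spec, generate_benchmark

BENCH_SEED = 20


def _patient(tmp_dir, **kwargs):
    spec = benchmark_spec(**kwargs)
    generate_benchmark(tmp_dir, spec)
    timeline = parse_summary(
        (pathlib.Path(tmp_dir) / "synth-summary.txt").read_text())
    return spec, timeline


def _segments(tmp_dir, spec, timeline, seed=BENCH_SEED):
    source = EDFDirectorySource(tmp_dir, timeline, channels=spec.channels)
    return build_segments(timeline, source, SegmentSpec(rng_seed=seed))


@pytest.fixture(scope="session")
def small_patient(tmp_path_factory):
    """1 eligible seizure, 4 channels: (dir, spec, timeline)."""
    d = tmp_path_factory.mktemp("small_patient")
    spec, timeline = _patient(d, seed=BENCH_SEED, n_seizures=1, n_channels=4)
    return d, spec, timeline


@pytest.fixture(scope="session")
def small_segments(small_patient):
    d, spec, timeline = small_patient
    return _segments(d, spec, timeline)


@pytest.fixture(scope="session")
def small_matrix(small_patient, small_segments):
    _, spec, timeline = small_patient
    return build_feature_matrix(small_segments, spec.channels, timeline.fs)


@pytest.fixture(scope="session")
def benchmark_patient(tmp_path_factory):
    """Full-scale synthetic patient: 23 channels, 4 seizures, ~27 h."""
    d = tmp_path_factory.mktemp("benchmark_patient")
    spec, timeline = _patient(d, seed=BENCH_SEED, n_seizures=4, n_channels=23)
    return d, spec, timeline


@pytest.fixture(scope="session")
def benchmark_segments(benchmark_patient):
    d, spec, timeline = benchmark_patient
    return _segments(d, spec, timeline)


@pytest.fixture(scope="session")
def benchmark_matrix(benchmark_patient, benchmark_segments):
    _, spec, timeline = benchmark_patient
    return build_feature_matrix(benchmark_segments, spec.channels, timeline.fs)


@pytest.fixture(scope="session")
def benchmark_cv(benchmark_matrix):
    from preictal.model import cross_validate
    return cross_validate(benchmark_matrix, k=10, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def null_patient(tmp_path_factory):
    """Same layout with class_effect = 0 (no pre-seizure signal), 4 channels."""
    d = tmp_path_factory.mktemp("null_patient")
    spec, timeline = _patient(d, seed=BENCH_SEED, n_seizures=4, n_channels=4,
                              class_effect=0.0)
    return d, spec, timeline


@pytest.fixture(scope="session")
def null_matrix(null_patient):
    d, spec, timeline = null_patient
    segments = _segments(d, spec, timeline)
    return build_feature_matrix(segments, spec.channels, timeline.fs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
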