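"""End-to-end orchestration: segment -> denoise -> features -> model -> alarm.

A run is driven by a flat key/value :class:`RunConfig` (loadable from YAML),
validated before any stage executes.  Every artifact is written to the
output directory together with the configuration and its hash, so a rerun
with the same config and inputs is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path

from . import alarm as alarm_mod
from . import entropy as entropy_mod
from . import model as model_mod
from .denoise import DenoiseSpec, preprocess_window, window_seed
from .io import parse_summary, _edf_header_labels
from .segmentation import (EDFDirectorySource, SegmentSpec, build_segments,
                           segment_manifest)

log = logging.getLogger("preictal")

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline",
           "find_summary", "load_timeline"]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run."""

    input_dir: str = "."
    out_dir: str = "run"
    seed: int = 0
    # segmentation
    int_minutes: float = 30.0
    isolation_hours: float = 2.0
    b_search_hours: float = 4.0
    b_pick_hours: float = 3.0
    window_s: float = 10.0
    # denoising
    denoise_enabled: bool = True
    denoise_wavelet: str = "db4"
    denoise_levels: int = 4
    denoise_threshold_mode: str = "soft"
    denoise_cutoff_hz: float = 30.0
    denoise_ensemble_size: int = 50
    denoise_noise_scale: float = 0.2
    denoise_max_imfs: int = 10
    denoise_strict_first_two: bool = False
    # entropy features
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    entropy_pen_m: int = 3
    entropy_pen_tau: int = 1
    entropy_wavelet: str = "db4"
    entropy_wen_levels: int = 4
    # classifier
    model_rounds: int = 100
    model_shrinkage: float = 0.1
    model_max_depth: int = 3
    model_rf_trees: int = 100
    model_init_mode: str = "logit"
    cv_folds: int = 10
    group_by_segment: bool = False
    # alarm post-processing
    alarm_k1: int = 3
    alarm_n1: int = 6
    alarm_k2: int = 5
    alarm_n2: int = 10

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        known = {f.name: f.type for f in fields(cls)}
        unknown = set(values) - set(known)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            cfg = cls(**values)
            cfg.segment_spec()
            cfg.denoise_spec()
            cfg.feature_params()
            cfg.model_params()
            cfg.alarm_spec()
        except (ValueError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml
        values = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(values, dict):
            raise ConfigError("config file must hold a flat key/value mapping")
        return cls.from_dict(values)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def segment_spec(self) -> SegmentSpec:
        return SegmentSpec(int_minutes=self.int_minutes,
                           isolation_hours=self.isolation_hours,
                           b_search_hours=self.b_search_hours,
                           b_pick_hours=self.b_pick_hours,
                           window_s=self.window_s,
                           rng_seed=self.seed)

    def denoise_spec(self) -> DenoiseSpec:
        return DenoiseSpec(wavelet=self.denoise_wavelet,
                           levels=self.denoise_levels,
                           threshold_mode=self.denoise_threshold_mode,
                           noise_freq_cutoff_hz=self.denoise_cutoff_hz,
                           ensemble_size=self.denoise_ensemble_size,
                           noise_scale=self.denoise_noise_scale,
                           max_imfs=self.denoise_max_imfs,
                           strict_first_two=self.denoise_strict_first_two)

    def feature_params(self) -> entropy_mod.FeatureParams:
        return entropy_mod.FeatureParams(m=self.entropy_m,
                                         r_factor=self.entropy_r_factor,
                                         pen_m=self.entropy_pen_m,
                                         pen_tau=self.entropy_pen_tau,
                                         wavelet=self.entropy_wavelet,
                                         wen_levels=self.entropy_wen_levels)

    def model_params(self) -> model_mod.ModelParams:
        return model_mod.ModelParams(n_rounds=self.model_rounds,
                                     shrinkage=self.model_shrinkage,
                                     max_depth=self.model_max_depth,
                                     rf_trees=self.model_rf_trees,
                                     init_mode=self.model_init_mode)

    def alarm_spec(self) -> alarm_mod.AlarmSpec:
        return alarm_mod.AlarmSpec(k1=self.alarm_k1, n1=self.alarm_n1,
                                   k2=self.alarm_k2, n2=self.alarm_n2)


def find_summary(input_dir: str | Path) -> Path:
    """Locate the annotation summary text file in a patient directory."""
    input_dir = Path(input_dir)
    candidates = sorted(input_dir.glob("*summary*.txt")) or sorted(
        p for p in input_dir.glob("*.txt") if "File Name:" in p.read_text())
    if not candidates:
        raise FileNotFoundError(f"no summary annotation file in {input_dir}")
    return candidates[0]


def load_timeline(input_dir: str | Path):
    return parse_summary(find_summary(input_dir).read_text())


def _denoise_segments(segments, cfg: RunConfig, fs: float):
    dspec = cfg.denoise_spec()
    for si, seg in enumerate(segments):
        n_win, n_ch, _ = seg.windows.shape
        for wi in range(n_win):
            for ci in range(n_ch):
                seg.windows[wi, ci] = preprocess_window(
                    seg.windows[wi, ci], dspec, fs=fs,
                    seed=window_seed(cfg.seed, si, wi, ci))
    return segments


def run_pipeline(cfg: RunConfig):
    """Execute all stages; returns (feature_matrix, cv_report, alarm_report)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    (out / "config.json").write_text(
        json.dumps({"hash": chash, **asdict(cfg)}, indent=2))

    def stage(name, fn, *args, **kwargs):
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
        return result

    timeline = stage("segmentation", load_timeline, cfg.input_dir)
    input_dir = Path(cfg.input_dir)
    first_edf = input_dir / timeline.files[0].file_id
    channels = [c for i, c in enumerate(_edf_header_labels(first_edf))
                if c not in _edf_header_labels(first_edf)[:i]]
    source = EDFDirectorySource(input_dir, timeline, channels=channels)
    segments = stage("segmentation", build_segments, timeline, source,
                     cfg.segment_spec())
    log.info("stage=segmentation config=%s segments=%d (A=%d, B=%d)", chash,
             len(segments), sum(s.label for s in segments),
             sum(1 - s.label for s in segments))
    segment_manifest(segments).to_csv(out / "segments.csv", index=False)

    fs = timeline.fs
    if cfg.denoise_enabled:
        segments = stage("denoise", _denoise_segments, segments, cfg, fs)
        log.info("stage=denoise config=%s ensemble=%d", chash,
                 cfg.denoise_ensemble_size)

    fm = stage("features", entropy_mod.build_feature_matrix, segments,
               channels, fs, cfg.feature_params())
    log.info("stage=features config=%s rows=%d cols=%d imputed=%d", chash,
             fm.shape[0], fm.shape[1], fm.n_imputed)
    entropy_mod.write_feature_csv(fm, out / "features.csv")

    report = stage("model", model_mod.cross_validate, fm, cfg.cv_folds,
                   cfg.model_params(), cfg.seed, cfg.group_by_segment)
    log.info("stage=model config=%s folds=%d accuracy=%.4f", chash,
             cfg.cv_folds, report.mean_metrics["accuracy"])
    (out / "cv_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    oof = fm.meta.copy()
    oof["oof_pred"] = report.oof_pred
    oof["oof_proba"] = report.oof_proba
    oof.to_csv(out / "oof_predictions.csv", index=False)

    alarm_report = stage("alarm", alarm_mod.alarm_from_oof, fm.meta,
                         report.oof_pred, cfg.alarm_spec())
    log.info("stage=alarm config=%s predicted=%d/%d false_alarms=%d", chash,
             alarm_report.n_predicted, alarm_report.n_seizures,
             alarm_report.n_false_alarms)
    (out / "alarm_report.json").write_text(
        json.dumps(alarm_report.to_dict(), indent=2))
    alarm_report.to_frame().to_csv(out / "alarm_table.csv", index=False)
    return fm, report, alarm_report
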