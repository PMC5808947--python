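"""End-to-end orchestration: mode auto-switching and artifact writing.

The pipeline first builds an activity-mode spectrogram of the whole
recording and runs the Doppler-power motion indicator on it; static
segments are routed to the breathing branch (re-processed with the
finer-resolution breathing CAF), moving segments to the activity branch
(windowed features, optionally classified with a trained model).
"""

from __future__ import annotations

import dataclasses
import json
import platform
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ._version import __version__ as _pkg_version
from .activity import (
    ClassifierModel,
    FeatureVector,
    PCASpec,
    pca_features,
    physical_features,
    predict,
    svd_features,
    window_spectrogram,
)
from .breathing import BreathingEstimate, SGFilterSpec, analyze_breathing
from .errors import DataError, ParameterError, PdsenseError
from .radar import (
    CAFConfig,
    DopplerSpectrogram,
    MotionSegments,
    motion_indicator,
    process_recording,
)
from .scene import BasebandRecording, SourceSpec

__all__ = ["PipelineConfig", "RunLog", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable bundle of every stage's parameters."""

    source: SourceSpec = field(default_factory=SourceSpec)
    caf_breathing: CAFConfig = field(default_factory=CAFConfig.breathing)
    caf_activity: CAFConfig = field(default_factory=CAFConfig.activity)
    motion_threshold_fraction: float = 0.10
    motion_reference_level: float | None = None
    #: Motion threshold as Doppler power relative to the squared direct-path
    #: level; calibrated midway (log scale) between the static and moving
    #: populations of the bundled scenes.  None falls back to the relative
    #: (waveform-amplitude) rule.
    motion_normalized_reference: float | None = 2e-3
    sg: SGFilterSpec = field(default_factory=SGFilterSpec)
    band_bpm: tuple[float, float] = (6.0, 30.0)
    pca: PCASpec = field(default_factory=PCASpec)
    feature_method: str = "svd"
    svm_c: float = 1.0
    svm_kernel: str = "linear"
    window_s: float = 4.0
    min_breathing_segment_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.band_bpm = tuple(self.band_bpm)  # type: ignore[assignment]
        if self.caf_breathing.doppler_bin_hz >= self.caf_activity.doppler_bin_hz:
            warnings.warn(
                "breathing-mode Doppler bins are not finer than activity-mode bins",
                stacklevel=2,
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        casts = {
            "source": SourceSpec,
            "caf_breathing": CAFConfig,
            "caf_activity": CAFConfig,
            "sg": SGFilterSpec,
            "pca": PCASpec,
        }
        for key, typ in casts.items():
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if not path.exists():
            raise DataError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise DataError(f"malformed config {path}: {exc}") from exc
        return cls.from_dict(data)


@dataclass
class RunLog:
    """Per-run provenance: parameters, stage timings, warnings, versions."""

    parameters: dict = field(default_factory=dict)
    timings_s: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    versions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.versions:
            import scipy
            import sklearn

            self.versions = {
                "pdsense": _pkg_version,
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "scikit-learn": sklearn.__version__,
                "python": platform.python_version(),
            }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True, default=str))
        return path


@dataclass
class PipelineResult:
    spectrogram: DopplerSpectrogram
    segments: MotionSegments
    breathing: list[BreathingEstimate]
    activity_features: list[FeatureVector]
    activity_labels: list[str]
    log: RunLog


def _stage(log: RunLog, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            log.timings_s[name] = round(time.perf_counter() - self.t0, 4)
            if exc is not None and isinstance(exc, PdsenseError):
                raise DataError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Timer()


def run_pipeline(
    cfg: PipelineConfig,
    ref: BasebandRecording,
    surv: BasebandRecording,
    belt: np.ndarray | None = None,
    belt_rate_hz: float = 2.0,
    classifier: ClassifierModel | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full two-stage chain on one recording pair.

    Static segments produce :class:`BreathingEstimate` objects (skipping
    segments shorter than ``cfg.min_breathing_segment_s`` with a warning);
    moving segments produce windowed feature vectors and, when a trained
    model is supplied, predicted activity labels.  All artifacts plus a
    :class:`RunLog` are written under ``out_dir`` when given.
    """
    log = RunLog(parameters=cfg.to_dict())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with _stage(log, "spectrogram"):
            spec = process_recording(ref, surv, cfg.caf_activity)

        with _stage(log, "motion_indicator"):
            segments = motion_indicator(
                spec,
                threshold_fraction=cfg.motion_threshold_fraction,
                reference_level=cfg.motion_reference_level,
                normalized_reference=(
                    None if cfg.motion_reference_level is not None
                    else cfg.motion_normalized_reference
                ),
            )

        breathing: list[BreathingEstimate] = []
        with _stage(log, "breathing"):
            for t0, t1 in segments.segments_of("static"):
                if t1 - t0 < cfg.min_breathing_segment_s:
                    warnings.warn(
                        f"static segment [{t0:.2f}, {t1:.2f}] s shorter than "
                        f"{cfg.min_breathing_segment_s:g} s; skipped",
                        stacklevel=2,
                    )
                    continue
                b_spec = process_recording(
                    ref,
                    surv,
                    cfg.caf_breathing,
                    start_s=max(t0, 0.0),
                    end_s=min(t1, surv.duration_s),
                )
                breathing.append(
                    analyze_breathing(
                        b_spec,
                        sg=cfg.sg,
                        band_bpm=cfg.band_bpm,
                        belt=belt,
                        belt_rate_hz=belt_rate_hz,
                    )
                )

        features: list[FeatureVector] = []
        labels: list[str] = []
        with _stage(log, "activity"):
            hop = spec.frame_hop_s
            for t0, t1 in segments.segments_of("moving"):
                sel = (spec.frame_times_s >= t0) & (spec.frame_times_s < t1)
                if np.count_nonzero(sel) < 1:
                    continue
                sub = DopplerSpectrogram(
                    values=spec.values[:, sel],
                    doppler_axis_hz=spec.doppler_axis_hz,
                    frame_times_s=spec.frame_times_s[sel],
                    config=spec.config,
                )
                try:
                    wins = window_spectrogram(sub, cfg.window_s)
                except DataError:
                    wins = [sub]  # moving burst shorter than one window
                for w in wins:
                    if cfg.feature_method == "svd":
                        features.append(svd_features(w, window_s=cfg.window_s))
                    elif cfg.feature_method == "pf":
                        features.append(physical_features(w, window_s=cfg.window_s))
                    elif cfg.feature_method == "pca":
                        if classifier is None or classifier.pca_basis is None:
                            raise ParameterError(
                                "feature_method 'pca' needs a classifier carrying its PCA basis"
                            )
                        features.append(
                            pca_features(w, cfg.pca, classifier.pca_basis, window_s=cfg.window_s)
                        )
                    else:
                        raise ParameterError(f"unknown feature method {cfg.feature_method!r}")
            if classifier is not None and features:
                labels = predict(classifier, features)

        log.warnings = [str(w.message) for w in caught]

    if out_dir is not None:
        from .io import write_features, write_spectrogram

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with _stage(log, "write_artifacts"):
            write_spectrogram(spec, out / "spectrogram.csv")
            seg_payload = {
                "segments": [
                    {"start_s": a, "end_s": b, "state": s} for a, b, s in segments.segments
                ],
                "threshold_fraction": segments.threshold_fraction,
            }
            (out / "segments.json").write_text(json.dumps(seg_payload, indent=1))
            for k, est in enumerate(breathing):
                _write_breathing(est, out / f"breathing_{k}")
            if features:
                write_features(features, out / "features.csv")
            if labels:
                (out / "predictions.json").write_text(json.dumps({"labels": labels}, indent=1))
        log.write(out / "runlog.json")

    return PipelineResult(
        spectrogram=spec,
        segments=segments,
        breathing=breathing,
        activity_features=features,
        activity_labels=labels,
        log=log,
    )


def _write_breathing(est: BreathingEstimate, base: Path) -> None:
    import pandas as pd

    wave = est.waveform
    raw = est.psi_raw
    df = pd.DataFrame({"time_s": wave.frame_times_s, "psi_smoothed": wave.psi})
    if raw is not None and len(raw.psi) == len(wave.psi):
        df["psi_raw"] = raw.psi
    if est.belt_resampled is not None and len(est.belt_resampled) == len(wave.psi):
        df["belt_resampled"] = est.belt_resampled
    df.to_csv(base.with_suffix(".csv"), index=False)
    summary = {
        "rate_bpm": None if not est.valid else est.rate_bpm,
        "valid": est.valid,
        "R": est.r_value,
        "MSE": est.mse,
        "search_band_bpm": list(est.search_band_bpm),
    }
    base.with_suffix(".json").write_text(json.dumps(summary, indent=1))
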