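"""Readers/writers for the pdsense on-disk formats.

* IQ container: one ``.iq`` file per channel -- interleaved little-endian
  32-bit float real/imag pairs -- plus a ``.json`` sidecar with channel,
  timing and ground-truth metadata.
* Spectrogram CSV: rows are Doppler bins (Hz labels), columns frame times.
* Feature table CSV: window_id, subject, label, method, f1..fk.
* Classifier archive: a directory with ``manifest.json`` plus the fitted
  pairwise SVMs serialized with joblib.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .activity import ClassifierModel, FeatureVector
from .errors import DataError, ParameterError
from .radar import CAFConfig, DopplerSpectrogram
from .scene import BasebandRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_spectrogram",
    "read_spectrogram",
    "write_features",
    "read_features",
    "save_model",
    "load_model",
]

FORMAT_VERSION = 1
_SIDECAR_REQUIRED = ("channel", "sample_rate_hz", "carrier_freq_hz", "duration_s")


def _sidecar_path(iq_path: Path) -> Path:
    return iq_path.with_suffix(".json")


def write_recording(rec: BasebandRecording, path: str | Path) -> Path:
    """Write ``<path>.iq`` + ``<path>.json``; returns the ``.iq`` path."""
    path = Path(path)
    iq_path = path if path.suffix == ".iq" else path.with_suffix(".iq")
    iq_path.parent.mkdir(parents=True, exist_ok=True)
    interleaved = np.empty(2 * len(rec.samples), dtype="<f4")
    interleaved[0::2] = rec.samples.real.astype(np.float32)
    interleaved[1::2] = rec.samples.imag.astype(np.float32)
    interleaved.tofile(iq_path)
    sidecar = {
        "format_version": FORMAT_VERSION,
        "writer": f"pdsense {_pkg_version}",
        "channel": rec.channel,
        "sample_rate_hz": rec.sample_rate_hz,
        "carrier_freq_hz": rec.carrier_freq_hz,
        "duration_s": rec.duration_s,
        "seed": rec.seed,
        "truth": rec.truth,
    }
    _sidecar_path(iq_path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return iq_path


def read_recording(path: str | Path) -> BasebandRecording:
    """Read an IQ container; validates the sidecar schema and sample count."""
    iq_path = Path(path)
    if iq_path.suffix != ".iq":
        iq_path = iq_path.with_suffix(".iq")
    if not iq_path.exists():
        raise DataError(f"IQ file not found: {iq_path}")
    sidecar_path = _sidecar_path(iq_path)
    if not sidecar_path.exists():
        raise DataError(f"sidecar not found: {sidecar_path}")
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"corrupt sidecar {sidecar_path}: {exc}") from exc
    for key in _SIDECAR_REQUIRED:
        if key not in meta:
            raise DataError(f"sidecar {sidecar_path} is missing required field {key!r}")
    raw = np.fromfile(iq_path, dtype="<f4")
    expected = 2 * int(round(meta["sample_rate_hz"] * meta["duration_s"]))
    if len(raw) != expected:
        raise DataError(
            f"{iq_path}: expected {expected} float32 values "
            f"({expected // 2} samples), found {len(raw)} -- truncated or corrupt"
        )
    samples = raw[0::2].astype(np.float64) + 1j * raw[1::2].astype(np.float64)
    return BasebandRecording(
        channel=meta["channel"],
        samples=samples,
        sample_rate_hz=float(meta["sample_rate_hz"]),
        carrier_freq_hz=float(meta["carrier_freq_hz"]),
        duration_s=float(meta["duration_s"]),
        seed=meta.get("seed"),
        truth=meta.get("truth", {}),
    )


# ---------------------------------------------------------------------------
# Spectrograms


def write_spectrogram(spec: DopplerSpectrogram, path: str | Path) -> Path:
    """CSV export: rows = Doppler bins (Hz), columns = frame times."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        cols = ",".join(f"t={t:.6f}" for t in spec.frame_times_s)
        fh.write(f"doppler_hz,{cols}\n")
        for i, f in enumerate(spec.doppler_axis_hz):
            row = ",".join(f"{v:.9g}" for v in spec.values[i, :])
            fh.write(f"{f:.9g},{row}\n")
    return path


def read_spectrogram(path: str | Path, config: CAFConfig | None = None) -> DopplerSpectrogram:
    path = Path(path)
    if not path.exists():
        raise DataError(f"spectrogram file not found: {path}")
    df = pd.read_csv(path)
    if df.columns[0] != "doppler_hz":
        raise DataError(f"{path}: first column must be 'doppler_hz'")
    try:
        times = np.array([float(c.split("=", 1)[1]) for c in df.columns[1:]])
    except (IndexError, ValueError) as exc:
        raise DataError(f"{path}: malformed frame-time headers") from exc
    return DopplerSpectrogram(
        values=df.iloc[:, 1:].to_numpy(dtype=float),
        doppler_axis_hz=df["doppler_hz"].to_numpy(dtype=float),
        frame_times_s=times,
        config=config,
    )


# ---------------------------------------------------------------------------
# Feature tables


def write_features(features: list[FeatureVector], path: str | Path) -> Path:
    if not features:
        raise ParameterError("no feature vectors to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    k = len(features[0].values)
    rows = []
    for i, f in enumerate(features):
        if len(f.values) != k:
            raise DataError("feature vectors have inconsistent lengths")
        row = {"window_id": i, "subject": f.subject, "label": f.label, "method": f.method}
        row.update({f"f{j + 1}": v for j, v in enumerate(f.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_features(path: str | Path) -> list[FeatureVector]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"feature file not found: {path}")
    df = pd.read_csv(path)
    needed = {"window_id", "subject", "label", "method"}
    if not needed.issubset(df.columns):
        raise DataError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    fcols.sort(key=lambda c: int(c[1:]))
    out = []
    for _, row in df.iterrows():
        subject = row["subject"]
        out.append(
            FeatureVector(
                method=row["method"],
                values=row[fcols].to_numpy(dtype=float),
                label=None if pd.isna(row["label"]) else str(row["label"]),
                subject=None if pd.isna(subject) else int(subject),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Classifier archive


def save_model(model: ClassifierModel, path: str | Path) -> Path:
    """Portable archive: manifest.json + joblib payload in one directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "writer": f"pdsense {_pkg_version}",
        "classes": model.classes,
        "C": model.C,
        "kernel": model.kernel,
        "num_classifiers": model.num_classifiers,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_std": model.scaler_std.tolist(),
        "has_pca_basis": model.pca_basis is not None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    joblib.dump(model, path / "model.joblib")
    return path


def load_model(path: str | Path) -> ClassifierModel:
    path = Path(path)
    manifest_path = path / "manifest.json"
    payload = path / "model.joblib"
    if not manifest_path.exists() or not payload.exists():
        raise DataError(f"{path} is not a pdsense model archive")
    manifest = json.loads(manifest_path.read_text())
    model: ClassifierModel = joblib.load(payload)
    if sorted(model.classes) != sorted(manifest["classes"]):
        raise DataError(f"{path}: manifest and payload disagree on classes")
    return model
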