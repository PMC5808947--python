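"""Moving-mode branch: Doppler-signature features and one-vs-one SVM.

Each 4 s spectrogram window is summarized by one of three feature vectors --
the leading singular values of the window (SVD), its projection onto a PCA
basis learned from the training split only, or six physical descriptors
(duration, Doppler bandwidth, signed Doppler peaks, energy, energy
asymmetry) -- and classified by a one-against-one ensemble of K(K-1)/2
binary soft-margin SVMs with majority voting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .errors import DataError, ParameterError
from .radar import CAFConfig, DopplerSpectrogram, process_recording

__all__ = [
    "FeatureVector",
    "PCASpec",
    "PCABasis",
    "ClassifierModel",
    "ConfusionMatrix",
    "window_spectrogram",
    "svd_features",
    "train_pca_basis",
    "pca_features",
    "physical_features",
    "FeatureCorpus",
    "build_feature_corpus",
    "train_ovo_svm",
    "predict",
    "evaluate_splits",
    "evaluate_inter_subject",
]

FEATURE_METHODS = ("svd", "pca", "pf")


@dataclass
class FeatureVector:
    """Per-window activity features; length is fixed within a method."""

    method: str
    values: np.ndarray
    window_s: float = 4.0
    label: str | None = None
    subject: int | None = None

    def __post_init__(self) -> None:
        if self.method not in FEATURE_METHODS:
            raise ParameterError(f"method must be one of {FEATURE_METHODS}")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.method == "pf" and len(self.values) != 6:
            raise ParameterError("physical feature vectors have exactly six entries")


@dataclass(frozen=True)
class PCASpec:
    """Energy-based truncation of the PCA basis: keep the smallest number of
    components reaching ``energy_fraction``, capped at ``max_components``."""

    energy_fraction: float = 0.90
    max_components: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.energy_fraction <= 1.0:
            raise ParameterError("energy_fraction must be in (0, 1]")
        if self.max_components < 1:
            raise ParameterError("max_components must be >= 1")


@dataclass
class PCABasis:
    """Doppler-profile eigenbasis fitted on training windows only."""

    components: np.ndarray  # (n_doppler, L) orthonormal columns
    eigenvalues: np.ndarray  # all eigenvalues, descending
    spec: PCASpec

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


# ---------------------------------------------------------------------------
# Windowing


def window_spectrogram(spec: DopplerSpectrogram, window_s: float = 4.0) -> list[DopplerSpectrogram]:
    """Cut the spectrogram into non-overlapping fixed-length windows.

    Frames are grouped by the time interval their centre falls in; every
    window is zero-padded on the right to ``round(window_s / hop)`` frames so
    feature vectors have a common size, and a trailing partial window is
    kept (zero-padded) rather than dropped.
    """
    if window_s <= 0:
        raise ParameterError("window_s must be positive")
    if spec.num_frames == 0:
        raise DataError("empty spectrogram")
    hop = spec.frame_hop_s
    T = spec.config.integration_time_s if spec.config is not None else hop
    t0 = spec.frame_times_s[0] - T / 2.0  # recording start
    coverage = (spec.frame_times_s[-1] + T / 2.0) - t0
    if coverage + 1e-9 < window_s:
        raise DataError(
            f"spectrogram covers {coverage:g} s, shorter than the {window_s:g} s window"
        )
    n_per = max(int(round(window_s / hop)), 1)
    rel = spec.frame_times_s - t0
    idx = np.floor(rel / window_s + 1e-9).astype(int)
    windows = []
    for w in range(idx.max() + 1):
        cols = np.flatnonzero(idx == w)
        if cols.size == 0:
            continue
        vals = spec.values[:, cols]
        times = spec.frame_times_s[cols]
        if vals.shape[1] < n_per:
            pad = n_per - vals.shape[1]
            vals = np.pad(vals, ((0, 0), (0, pad)))
            times = np.concatenate([times, times[-1] + hop * np.arange(1, pad + 1)])
        windows.append(
            DopplerSpectrogram(
                values=vals,
                doppler_axis_hz=spec.doppler_axis_hz.copy(),
                frame_times_s=times,
                config=spec.config,
            )
        )
    return windows


def _window_values(window: DopplerSpectrogram | np.ndarray) -> np.ndarray:
    if isinstance(window, DopplerSpectrogram):
        return window.values
    return np.asarray(window, dtype=float)


# ---------------------------------------------------------------------------
# Features


def svd_features(window: DopplerSpectrogram | np.ndarray, rank: int = 10, window_s: float = 4.0) -> FeatureVector:
    """Leading singular values of the window, descending, zero-padded to ``rank``."""
    D = _window_values(window)
    if D.size == 0:
        raise DataError("empty window")
    s = np.linalg.svd(D, compute_uv=False)
    out = np.zeros(rank)
    k = min(rank, len(s))
    out[:k] = s[:k]
    return FeatureVector(method="svd", values=out, window_s=window_s)


def train_pca_basis(
    windows: list[DopplerSpectrogram | np.ndarray], spec: PCASpec | None = None
) -> PCABasis:
    """Fit the Doppler-profile PCA basis on (training) windows.

    Each window is column-mean-removed and the Doppler x Doppler covariance
    is accumulated over all training columns; L is the smallest component
    count reaching ``energy_fraction`` of the eigenvalue energy, capped at
    ``max_components``.
    """
    spec = spec or PCASpec()
    if not windows:
        raise ParameterError("need at least one training window")
    mats = [_window_values(w) for w in windows]
    n_dopp = mats[0].shape[0]
    cov = np.zeros((n_dopp, n_dopp))
    n_cols = 0
    for D in mats:
        if D.shape[0] != n_dopp:
            raise DataError("training windows have mismatched Doppler axes")
        Dc = D - D.mean(axis=0, keepdims=True)
        cov += Dc @ Dc.T
        n_cols += D.shape[1]
    cov /= max(n_cols, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    total = evals.sum()
    if total <= 0:
        L = 1
    else:
        cum = np.cumsum(evals) / total
        L = int(np.searchsorted(cum, spec.energy_fraction - 1e-12) + 1)
    L = min(L, spec.max_components, n_dopp)
    return PCABasis(components=evecs[:, :L], eigenvalues=evals, spec=spec)


def pca_features(
    window: DopplerSpectrogram | np.ndarray,
    spec: PCASpec | None = None,
    basis: PCABasis | None = None,
    window_s: float = 4.0,
) -> FeatureVector:
    """Project the column-demeaned window onto the trained basis.

    The (n_frames x L) projection is flattened and zero-padded to
    ``n_frames * max_components`` so the feature length does not depend on
    the energy-selected L.
    """
    if basis is None:
        raise ParameterError("pca_features requires a basis trained on the training split")
    spec = spec or basis.spec
    D = _window_values(window)
    if D.shape[0] != basis.components.shape[0]:
        raise DataError(
            f"window has {D.shape[0]} Doppler bins but the basis was trained with "
            f"{basis.components.shape[0]}"
        )
    Dc = D - D.mean(axis=0, keepdims=True)
    proj = Dc.T @ basis.components  # (n_frames, L)
    out = np.zeros((D.shape[1], spec.max_components))
    out[:, : proj.shape[1]] = proj
    return FeatureVector(method="pca", values=out.ravel(), window_s=window_s)


def physical_features(
    window: DopplerSpectrogram | np.ndarray,
    doppler_axis_hz: np.ndarray | None = None,
    hop_s: float = 1.0,
    window_s: float = 4.0,
    threshold_fraction: float = 0.10,
) -> FeatureVector:
    """Six physical descriptors of the windowed Doppler signature.

    1. active duration (s): frames whose non-zero-Doppler power exceeds 10%
       of the window's peak frame power;
    2. Doppler bandwidth (Hz): frequency extent of bins active above 10% of
       the window's peak magnitude;
    3. peak positive Doppler (Hz) among active bins (0 if none);
    4. peak negative Doppler (Hz) among active bins (0 if none);
    5. total spectrogram energy;
    6. positive/negative Doppler energy ratio, softened by a small fraction
       of the total energy so a one-sided signature stays finite (1 for an
       all-zero window).
    """
    if isinstance(window, DopplerSpectrogram):
        D = window.values
        axis = window.doppler_axis_hz
        hop_s = window.frame_hop_s
    else:
        D = np.asarray(window, dtype=float)
        if doppler_axis_hz is None:
            raise ParameterError("doppler_axis_hz required for a bare matrix")
        axis = np.asarray(doppler_axis_hz, dtype=float)
    if D.size == 0:
        raise DataError("empty window")
    zero_bin = int(np.argmin(np.abs(axis)))
    bin_hz = float(np.median(np.diff(axis))) if len(axis) > 1 else 1.0

    total_energy = float(np.sum(D**2))
    if total_energy == 0:
        return FeatureVector(
            method="pf", values=np.array([0.0, 0.0, 0.0, 0.0, 0.0, 1.0]), window_s=window_s
        )

    mask = np.ones(len(axis), dtype=bool)
    mask[zero_bin] = False
    frame_power = np.sum(D[mask, :] ** 2, axis=0)
    duration = float(np.count_nonzero(frame_power > threshold_fraction * frame_power.max()) * hop_s)

    active_bins = np.flatnonzero(D.max(axis=1) > threshold_fraction * D.max())
    f_active = axis[active_bins]
    bandwidth = float(f_active.max() - f_active.min() + bin_hz) if f_active.size else 0.0
    pos = f_active[f_active > 0]
    neg = f_active[f_active < 0]
    peak_pos = float(pos.max()) if pos.size else 0.0
    peak_neg = float(neg.min()) if neg.size else 0.0

    e_pos = float(np.sum(D[axis > 0, :] ** 2))
    e_neg = float(np.sum(D[axis < 0, :] ** 2))
    soften = 1e-3 * total_energy
    ratio = (e_pos + soften) / (e_neg + soften)
    values = np.array([duration, bandwidth, peak_pos, peak_neg, total_energy, ratio])
    return FeatureVector(method="pf", values=values, window_s=window_s)


# ---------------------------------------------------------------------------
# Feature corpus (windows + labels; features computed per split)


@dataclass
class FeatureCorpus:
    """Windowed spectrograms with labels/subjects; features are computed per
    train/test split so the PCA basis never sees test windows."""

    windows: list[np.ndarray]
    labels: list[str]
    subjects: list[int]
    doppler_axis_hz: np.ndarray
    hop_s: float = 1.0
    window_s: float = 4.0
    svd_rank: int = 10
    pca_spec: PCASpec = field(default_factory=PCASpec)

    def __post_init__(self) -> None:
        if not (len(self.windows) == len(self.labels) == len(self.subjects)):
            raise ParameterError("windows, labels and subjects lengths differ")

    def __len__(self) -> int:
        return len(self.windows)

    def features(self, method: str, idx: np.ndarray, basis: PCABasis | None = None) -> np.ndarray:
        if method == "svd":
            rows = [svd_features(self.windows[i], rank=self.svd_rank).values for i in idx]
        elif method == "pca":
            if basis is None:
                raise ParameterError("pca features need a basis")
            rows = [pca_features(self.windows[i], self.pca_spec, basis).values for i in idx]
        elif method == "pf":
            rows = [
                physical_features(
                    self.windows[i], self.doppler_axis_hz, hop_s=self.hop_s
                ).values
                for i in idx
            ]
        else:
            raise ParameterError(f"unknown feature method {method!r}")
        return np.vstack(rows)


def build_feature_corpus(
    entries: Sequence,
    cfg: CAFConfig | None = None,
    window_s: float = 4.0,
    svd_rank: int = 10,
    pca_spec: PCASpec | None = None,
) -> FeatureCorpus:
    """Process corpus scene entries into a windowed feature corpus.

    Each entry (see :class:`pdsense.scene.CorpusEntry`) is realized, run
    through the CLEANed CAF -> spectrogram chain, and cut into windows; only
    the window matrices are retained, so scene IQ buffers are released as
    soon as each recording has been processed.
    """
    cfg = cfg or CAFConfig.activity()
    windows: list[np.ndarray] = []
    labels: list[str] = []
    subjects: list[int] = []
    axis = None
    hop = cfg.hop
    for e in entries:
        ref, surv = e.realize()
        spec = process_recording(ref, surv, cfg)
        axis = spec.doppler_axis_hz
        hop = spec.frame_hop_s
        for w in window_spectrogram(spec, window_s):
            windows.append(w.values)
            labels.append(e.label)
            subjects.append(e.subject)
    if axis is None:
        raise ParameterError("empty corpus")
    return FeatureCorpus(
        windows=windows,
        labels=labels,
        subjects=subjects,
        doppler_axis_hz=axis,
        hop_s=hop,
        window_s=window_s,
        svd_rank=svd_rank,
        pca_spec=pca_spec or PCASpec(),
    )


# ---------------------------------------------------------------------------
# One-vs-one SVM ensemble


@dataclass
class ClassifierModel:
    """K(K-1)/2 pairwise soft-margin SVMs with majority-vote prediction."""

    classes: list[str]
    classifiers: dict[tuple[str, str], SVC]
    C: float
    kernel: str
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    pca_basis: PCABasis | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def num_classifiers(self) -> int:
        return len(self.classifiers)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_std


def _as_matrix(features: list[FeatureVector] | np.ndarray) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(features, np.ndarray):
        return np.atleast_2d(features), None
    X = np.vstack([f.values for f in features])
    labels = [f.label for f in features]
    return X, labels  # type: ignore[return-value]


def train_ovo_svm(
    features: list[FeatureVector] | np.ndarray,
    labels: list[str] | None = None,
    C: float = 1.0,
    kernel: str = "linear",
) -> ClassifierModel:
    """Train one binary SVM per unordered class pair (15 for six classes).

    Features are standardized with training-set statistics; each pairwise
    classifier solves the soft-margin problem min 1/2 w'w + C sum(xi).
    """
    X, inferred = _as_matrix(features)
    y = list(labels) if labels is not None else inferred
    if y is None or any(l is None for l in y):
        raise ParameterError("training features must carry labels")
    if len(y) != X.shape[0]:
        raise ParameterError("label count does not match feature count")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ParameterError("need at least two classes to train")
    y_arr = np.asarray(y)
    for c in classes:
        if np.count_nonzero(y_arr == c) < 2:
            raise ParameterError(f"class {c!r} has fewer than two training samples")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std
    classifiers: dict[tuple[str, str], SVC] = {}
    for a, b in itertools.combinations(classes, 2):
        sel = (y_arr == a) | (y_arr == b)
        clf = SVC(C=C, kernel=kernel)
        clf.fit(Xs[sel], y_arr[sel])
        classifiers[(a, b)] = clf
    return ClassifierModel(
        classes=classes,
        classifiers=classifiers,
        C=C,
        kernel=kernel,
        scaler_mean=mean,
        scaler_std=std,
        manifest={"n_train": int(X.shape[0]), "classes": classes, "C": C, "kernel": kernel},
    )


def predict(model: ClassifierModel, features: list[FeatureVector] | np.ndarray) -> list[str]:
    """Majority vote over all pairwise classifiers.

    Each classifier casts one vote per sample; ties are broken by the larger
    summed signed decision margin accumulated over all pairs.
    """
    X, _ = _as_matrix(features)
    if X.shape[1] != len(model.scaler_mean):
        raise DataError(
            f"feature length {X.shape[1]} does not match the model's {len(model.scaler_mean)}"
        )
    Xs = model.standardize(X)
    n = X.shape[0]
    cls_index = {c: k for k, c in enumerate(model.classes)}
    votes = np.zeros((n, len(model.classes)))
    margins = np.zeros((n, len(model.classes)))
    for (a, b), clf in model.classifiers.items():
        df = clf.decision_function(Xs)
        # SVC orders classes lexicographically: positive margin favours b.
        ia, ib = cls_index[a], cls_index[b]
        votes[np.arange(n), np.where(df > 0, ib, ia)] += 1
        margins[:, ib] += df
        margins[:, ia] -= df
    out = []
    for i in range(n):
        v = votes[i]
        best = np.flatnonzero(v == v.max())
        if len(best) == 1:
            out.append(model.classes[best[0]])
        else:
            out.append(model.classes[best[np.argmax(margins[i, best])]])
    return out


# ---------------------------------------------------------------------------
# Evaluation protocols


@dataclass
class ConfusionMatrix:
    """counts[true, predicted] (mean counts under repeated random splits)."""

    counts: np.ndarray
    classes: list[str]

    @property
    def per_class_accuracy(self) -> np.ndarray:
        row = self.counts.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, np.diag(self.counts) / row, np.nan)

    @property
    def overall_accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total > 0 else float("nan")

    def normalized(self) -> np.ndarray:
        row = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(row > 0, self.counts / row, 0.0)


@dataclass
class SplitEvaluation:
    method: str
    confusion: ConfusionMatrix
    mean_accuracy: float
    accuracy_by_train_size: dict[int, float]
    repeats: int


def _fit_predict(
    corpus: FeatureCorpus,
    method: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    C: float,
    kernel: str,
) -> list[str]:
    basis = None
    if method == "pca":
        basis = train_pca_basis([corpus.windows[i] for i in train_idx], corpus.pca_spec)
    X_train = corpus.features(method, train_idx, basis)
    X_test = corpus.features(method, test_idx, basis)
    y_train = [corpus.labels[i] for i in train_idx]
    model = train_ovo_svm(X_train, y_train, C=C, kernel=kernel)
    model.pca_basis = basis
    return predict(model, X_test)


def evaluate_splits(
    corpus: FeatureCorpus,
    method: str = "svd",
    n_train_per_class: int = 20,
    n_test_per_class: int = 10,
    repeats: int = 10,
    seed: int | None = None,
    C: float = 1.0,
    kernel: str = "linear",
    train_sizes: tuple[int, ...] = (),
) -> SplitEvaluation:
    """Repeated stratified random splits: mean confusion matrix and accuracy.

    With ``train_sizes`` the accuracy-vs-training-size curve is evaluated as
    well (same ``n_test_per_class`` held out each time).
    """
    if method not in FEATURE_METHODS:
        raise ParameterError(f"unknown feature method {method!r}")
    labels = np.asarray(corpus.labels)
    classes = sorted(set(corpus.labels))
    by_class = {c: np.flatnonzero(labels == c) for c in classes}
    need = n_train_per_class + n_test_per_class
    for c, idx in by_class.items():
        if len(idx) < need:
            raise ParameterError(
                f"class {c!r} has {len(idx)} windows, fewer than the requested {need}"
            )
    rng = np.random.default_rng(seed)
    k = len(classes)
    cls_index = {c: i for i, c in enumerate(classes)}

    def run(n_train: int) -> tuple[np.ndarray, float]:
        counts = np.zeros((k, k))
        accs = []
        for _ in range(repeats):
            train_idx, test_idx = [], []
            for c in classes:
                perm = rng.permutation(by_class[c])
                train_idx.extend(perm[:n_train])
                test_idx.extend(perm[n_train : n_train + n_test_per_class])
            train_idx, test_idx = np.asarray(train_idx), np.asarray(test_idx)
            pred = _fit_predict(corpus, method, train_idx, test_idx, C, kernel)
            truth = [corpus.labels[i] for i in test_idx]
            hit = 0
            for t, p in zip(truth, pred):
                counts[cls_index[t], cls_index[p]] += 1
                hit += t == p
            accs.append(hit / len(truth))
        return counts / repeats, float(np.mean(accs))

    counts, acc = run(n_train_per_class)
    curve = {}
    for n in train_sizes:
        if n == n_train_per_class:
            curve[n] = acc
        else:
            _, curve[n] = run(n)
    return SplitEvaluation(
        method=method,
        confusion=ConfusionMatrix(counts=counts, classes=classes),
        mean_accuracy=acc,
        accuracy_by_train_size=curve,
        repeats=repeats,
    )


def evaluate_inter_subject(
    corpus: FeatureCorpus,
    method: str = "svd",
    C: float = 1.0,
    kernel: str = "linear",
) -> dict:
    """Leave-one-subject-out: train on the other subjects, test on each one."""
    subjects = sorted(set(corpus.subjects))
    if len(subjects) < 2:
        raise ParameterError("inter-subject evaluation needs at least two subjects")
    subj = np.asarray(corpus.subjects)
    per_subject = {}
    for s in subjects:
        test_idx = np.flatnonzero(subj == s)
        train_idx = np.flatnonzero(subj != s)
        pred = _fit_predict(corpus, method, train_idx, test_idx, C, kernel)
        truth = [corpus.labels[i] for i in test_idx]
        per_subject[s] = float(np.mean([t == p for t, p in zip(truth, pred)]))
    return {
        "per_subject": per_subject,
        "mean_accuracy": float(np.mean(list(per_subject.values()))),
    }
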