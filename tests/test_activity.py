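"""Windowing, SVD/PCA/physical features and the one-vs-one SVM ensemble."""

import numpy as np
import pytest
from sklearn.svm import SVC

from pdsense import (
    CAFConfig,
    DataError,
    DopplerSpectrogram,
    ParameterError,
    PCASpec,
    evaluate_inter_subject,
    evaluate_splits,
    pca_features,
    physical_features,
    predict,
    svd_features,
    train_ovo_svm,
    train_pca_basis,
    window_spectrogram,
)
from pdsense.activity import FeatureCorpus, FeatureVector


def _spec(n_frames, n_dopp=9, hop=1.0, fill=None, T=1.0):
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 1, (n_dopp, n_frames)) if fill is None else np.full(
        (n_dopp, n_frames), float(fill)
    )
    axis = (np.arange(n_dopp) - n_dopp // 2) * 1.0
    return DopplerSpectrogram(
        values=vals,
        doppler_axis_hz=axis,
        frame_times_s=T / 2 + hop * np.arange(n_frames),
        config=CAFConfig(integration_time_s=T, doppler_span_hz=n_dopp // 2, hop_s=hop),
    )


class TestWindowing:
    def test_eight_seconds_two_windows(self):
        wins = window_spectrogram(_spec(8), 4.0)
        assert len(wins) == 2
        assert all(w.values.shape[1] == 4 for w in wins)

    def test_four_seconds_single_window_identical(self):
        spec = _spec(4)
        wins = window_spectrogram(spec, 4.0)
        assert len(wins) == 1
        assert np.array_equal(wins[0].values, spec.values)

    def test_ten_seconds_three_windows_third_padded(self):
        spec = _spec(10)
        wins = window_spectrogram(spec, 4.0)
        assert len(wins) == 3
        assert wins[2].values.shape[1] == 4
        assert np.all(wins[2].values[:, 2:] == 0)  # padding columns
        # energy of the first two windows preserved exactly
        e = np.sum(spec.values[:, :8] ** 2)
        assert np.sum(wins[0].values**2) + np.sum(wins[1].values**2) == pytest.approx(e)

    def test_too_short_input_rejected(self):
        with pytest.raises(DataError):
            window_spectrogram(_spec(2), 4.0)


class TestSvdFeatures:
    def test_rank_one_window_single_singular_value(self):
        u = np.ones(6) / np.sqrt(6)
        v = np.ones(4) / 2.0
        f = svd_features(np.outer(u, v), rank=5)
        assert f.values[0] == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(f.values[1:], 0.0, atol=1e-12)

    def test_zero_window_zero_vector(self):
        f = svd_features(np.zeros((6, 4)), rank=5)
        assert np.all(f.values == 0)

    def test_singular_values_match_eigen_oracle(self):
        """sigma_i^2 equal eigenvalues of D D^T (independent eigh oracle)."""
        rng = np.random.default_rng(5)
        D = rng.normal(size=(32, 32))
        f = svd_features(D, rank=32)
        evals = np.sort(np.linalg.eigvalsh(D @ D.T))[::-1]
        assert np.allclose(f.values**2, evals, atol=1e-8 * evals[0])

    def test_descending_and_fixed_length(self):
        rng = np.random.default_rng(6)
        f = svd_features(rng.normal(size=(12, 5)), rank=10)
        assert len(f.values) == 10
        assert np.all(np.diff(f.values) <= 1e-12)


class TestPcaFeatures:
    def test_complete_basis_preserves_variance(self):
        rng = np.random.default_rng(7)
        wins = [rng.normal(size=(6, 5)) for _ in range(4)]
        basis = train_pca_basis(wins, PCASpec(energy_fraction=1.0, max_components=6))
        total_in, total_out = 0.0, 0.0
        for D in wins:
            Dc = D - D.mean(axis=0, keepdims=True)
            total_in += np.sum(Dc**2)
            total_out += np.sum((Dc.T @ basis.components) ** 2)
        assert total_out == pytest.approx(total_in, rel=1e-8)

    def test_rank_one_data_needs_single_component(self):
        rng = np.random.default_rng(8)
        direction = rng.normal(size=6)
        wins = [np.outer(direction, rng.normal(size=5)) for _ in range(3)]
        basis = train_pca_basis(wins, PCASpec(energy_fraction=0.90))
        assert basis.n_components == 1

    def test_projected_variances_match_covariance_oracle(self):
        """Top-L projected variances equal top-L eigenvalues of the brute
        covariance matrix accumulated column by column."""
        rng = np.random.default_rng(9)
        wins = [rng.normal(size=(8, 6)) for _ in range(5)]
        spec = PCASpec(energy_fraction=1.0, max_components=3)
        basis = train_pca_basis(wins, spec)
        cols = np.hstack([D - D.mean(axis=0, keepdims=True) for D in wins])
        cov = cols @ cols.T / cols.shape[1]
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        proj_var = np.diag(basis.components.T @ cov @ basis.components)
        assert np.allclose(proj_var, evals[:3], rtol=1e-8)

    def test_basis_function_of_training_windows_only(self):
        rng = np.random.default_rng(10)
        train = [rng.normal(size=(6, 5)) for _ in range(4)]
        other = [1e6 * rng.normal(size=(6, 5)) for _ in range(4)]
        b1 = train_pca_basis(train)
        _ = train_pca_basis(other)  # unrelated windows, e.g. a test split
        b2 = train_pca_basis(train)
        assert np.array_equal(b1.components, b2.components)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(11)
        basis = train_pca_basis([rng.normal(size=(6, 5))])
        with pytest.raises(DataError):
            pca_features(rng.normal(size=(8, 5)), basis=basis)

    def test_feature_length_independent_of_selected_components(self):
        rng = np.random.default_rng(12)
        spec = PCASpec(energy_fraction=0.5, max_components=10)
        wins = [rng.normal(size=(8, 6)) for _ in range(3)]
        basis = train_pca_basis(wins, spec)
        f = pca_features(wins[0], spec, basis)
        assert len(f.values) == 6 * 10


class TestPhysicalFeatures:
    AXIS = np.arange(-4.0, 5.0)

    def test_zero_window_sentinel(self):
        f = physical_features(np.zeros((9, 8)), self.AXIS, hop_s=0.5)
        assert np.allclose(f.values, [0, 0, 0, 0, 0, 1])

    def test_single_positive_tone(self):
        axis = np.arange(-8.0, 9.0)
        D = np.zeros((17, 8))
        D[np.argmin(np.abs(axis - 6.0)), :] = 1.0
        f = physical_features(D, axis, hop_s=0.5)
        duration, bandwidth, peak_pos, peak_neg, energy, ratio = f.values
        assert duration == pytest.approx(8 * 0.5)
        assert bandwidth == pytest.approx(1.0)  # one bin
        assert peak_pos == pytest.approx(6.0)
        assert peak_neg == 0.0
        assert energy == pytest.approx(8.0)
        assert ratio > 100.0

    def test_sitting_mirror_of_standing_flips_ratio(self):
        axis = self.AXIS
        up = np.zeros((9, 6))
        up[6, :3] = 1.0  # +2 Hz transient
        down = up[::-1, :].copy()
        r_up = physical_features(up, axis, hop_s=0.5).values[5]
        r_down = physical_features(down, axis, hop_s=0.5).values[5]
        assert r_up > 1.0 > r_down

    def test_walking_lasts_longer_than_sitting(self, small_corpus):
        """Corpus ground truth: walking windows have the longer active time."""
        labels = np.asarray(small_corpus.labels)
        walk_idx = np.flatnonzero(labels == "walking")
        sit_idx = np.flatnonzero(labels == "sitting")
        durations = {
            i: physical_features(
                small_corpus.windows[i], small_corpus.doppler_axis_hz,
                hop_s=small_corpus.hop_s,
            ).values[0]
            for i in np.concatenate([walk_idx, sit_idx])
        }
        wins = sum(
            durations[w] > durations[s] for w in walk_idx for s in sit_idx
        )
        assert wins / (len(walk_idx) * len(sit_idx)) >= 0.95


class TestOvoSvm:
    @staticmethod
    def _gaussian_features(k_classes, n_per_class, seed=0, spread=8.0):
        rng = np.random.default_rng(seed)
        feats = []
        for k in range(k_classes):
            center = spread * rng.normal(size=4)
            for _ in range(n_per_class):
                feats.append(
                    FeatureVector(
                        method="svd",
                        values=center + rng.normal(size=4),
                        label=f"c{k}",
                        subject=0,
                    )
                )
        return feats

    def test_six_classes_fifteen_classifiers(self):
        model = train_ovo_svm(self._gaussian_features(6, 4))
        assert model.num_classifiers == 15

    def test_two_classes_one_classifier(self):
        model = train_ovo_svm(self._gaussian_features(2, 4))
        assert model.num_classifiers == 1

    def test_separable_clusters_perfect_training_accuracy(self):
        feats = self._gaussian_features(6, 6, seed=3)
        model = train_ovo_svm(feats)
        pred = predict(model, feats)
        assert pred == [f.label for f in feats]

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            train_ovo_svm(self._gaussian_features(1, 5))

    def test_vote_budget_is_k_choose_2(self):
        """Each sample receives exactly K(K-1)/2 = 15 pairwise votes."""
        feats = self._gaussian_features(6, 4, seed=4)
        model = train_ovo_svm(feats)
        X = np.vstack([f.values for f in feats])
        Xs = model.standardize(X)
        votes = np.zeros(len(X))
        for clf in model.classifiers.values():
            votes += 1  # one decision per pair per sample
            clf.decision_function(Xs)
        assert np.all(votes == 15)

    def test_predictions_match_sklearn_ovo_reference(self):
        """Independent route: sklearn's own one-vs-one voting agrees."""
        feats = self._gaussian_features(5, 8, seed=6, spread=6.0)
        model = train_ovo_svm(feats)
        X = np.vstack([f.values for f in feats])
        y = [f.label for f in feats]
        ours = predict(model, X)
        sk = SVC(C=1.0, kernel="linear", decision_function_shape="ovo")
        sk.fit(model.standardize(X), y)
        theirs = list(sk.predict(model.standardize(X)))
        agree = np.mean([a == b for a, b in zip(ours, theirs)])
        assert agree >= 0.98

    def test_dimension_mismatch_rejected(self):
        model = train_ovo_svm(self._gaussian_features(2, 4))
        with pytest.raises(DataError):
            predict(model, np.zeros((1, 9)))


def _toy_corpus(k_classes=3, n_per_class=12, seed=0, spread=6.0, n_subjects=2):
    rng = np.random.default_rng(seed)
    windows, labels, subjects = [], [], []
    centers = {k: spread * rng.normal(size=(4, 3)) for k in range(k_classes)}
    for k in range(k_classes):
        for i in range(n_per_class):
            windows.append(centers[k] + 0.3 * rng.normal(size=(4, 3)))
            labels.append(f"c{k}")
            subjects.append(i % n_subjects)
    return FeatureCorpus(
        windows=windows,
        labels=labels,
        subjects=subjects,
        doppler_axis_hz=np.array([-1.0, 0.0, 1.0, 2.0]),
        hop_s=1.0,
        svd_rank=4,
    )


class TestEvaluationProtocols:
    def test_separable_corpus_perfect_accuracy(self):
        corpus = _toy_corpus()
        res = evaluate_splits(corpus, "svd", n_train_per_class=8, n_test_per_class=4,
                              repeats=3, seed=0)
        assert res.mean_accuracy == 1.0
        assert res.confusion.overall_accuracy == 1.0

    def test_confusion_rows_sum_to_test_counts(self):
        corpus = _toy_corpus()
        res = evaluate_splits(corpus, "svd", n_train_per_class=8, n_test_per_class=4,
                              repeats=3, seed=0)
        assert np.allclose(res.confusion.counts.sum(axis=1), 4.0)
        assert np.allclose(res.confusion.normalized().sum(axis=1), 1.0)

    def test_shuffled_labels_fall_to_chance(self):
        corpus = _toy_corpus(k_classes=3, n_per_class=20, seed=2)
        rng = np.random.default_rng(3)
        corpus.labels = list(rng.permutation(corpus.labels))
        res = evaluate_splits(corpus, "svd", n_train_per_class=12, n_test_per_class=6,
                              repeats=10, seed=4)
        n_test = 18 * 10
        p = 1.0 / 3.0
        sigma = np.sqrt(p * (1 - p) / n_test)
        assert abs(res.mean_accuracy - p) < 3 * sigma + 0.02

    def test_insufficient_samples_rejected(self):
        corpus = _toy_corpus(n_per_class=5)
        with pytest.raises(ParameterError):
            evaluate_splits(corpus, "svd", n_train_per_class=20, n_test_per_class=10)

    def test_accuracy_curve_covers_requested_sizes(self):
        corpus = _toy_corpus(n_per_class=12)
        res = evaluate_splits(corpus, "svd", n_train_per_class=6, n_test_per_class=3,
                              repeats=2, seed=0, train_sizes=(4, 6, 8))
        assert set(res.accuracy_by_train_size) == {4, 6, 8}

    def test_inter_subject_one_entry_per_subject(self):
        corpus = _toy_corpus(n_subjects=3, n_per_class=12)
        out = evaluate_inter_subject(corpus, "svd")
        assert set(out["per_subject"]) == {0, 1, 2}

    def test_exchangeable_subjects_match_within_subject_accuracy(self):
        """Subjects drawn from one distribution: leave-one-subject-out is as
        good as random splits on separable data."""
        corpus = _toy_corpus(n_subjects=2, n_per_class=16)
        out = evaluate_inter_subject(corpus, "svd")
        assert out["mean_accuracy"] == pytest.approx(1.0, abs=0.05)

    def test_single_subject_rejected(self):
        corpus = _toy_corpus(n_subjects=1)
        with pytest.raises(ParameterError):
            evaluate_inter_subject(corpus, "svd")

    def test_feature_determinism(self, small_corpus):
        idx = np.arange(min(4, len(small_corpus)))
        for method in ("svd", "pf"):
            a = small_corpus.features(method, idx)
            b = small_corpus.features(method, idx)
            assert np.array_equal(a, b)
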