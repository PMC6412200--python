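"""Relief-F, weighted SVM grid search and the dual-model bundle."""

import numpy as np
import pytest

import wearact as wa
from wearact.classify import (
    SvmConfig,
    class_weights,
    grid_search_svm,
    predict_windows,
    rank_features,
    relief_f,
    train_bundle,
)
from wearact.core_io import CHANNELS_3, Recording


def brute_force_relief(X, y, k):
    """Literal per-instance Relief-F update rule (independent oracle)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, d = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Z = (X - X.min(axis=0)) / span
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    W = np.zeros(d)
    for i in range(n):
        di = np.abs(Z - Z[i]).sum(axis=1)
        for c in classes:
            idx = [j for j in range(n) if y[j] == c and j != i]
            idx.sort(key=lambda j: (di[j], j))
            near = idx[:k]
            diff = np.abs(Z[near] - Z[i]).sum(axis=0) / (k * n)
            if c == y[i]:
                W -= diff
            else:
                W += priors[c] / (1 - priors[y[i]]) * diff
    return W


class TestClassWeights:
    def test_sum_equals_n_classes(self):
        y = ["a"] * 10 + ["b"] * 30 + ["c"] * 60
        w = class_weights(y)
        assert sum(w.values()) == pytest.approx(3.0)
        assert w["a"] > w["b"] > w["c"]

    def test_invariant_to_doubling(self):
        y = ["a"] * 5 + ["b"] * 15
        assert class_weights(y) == class_weights(y * 2)


class TestReliefF:
    def test_informative_feature_beats_noise(self):
        """Across 100 seeded draws the separating feature must outrank the
        pure-noise feature in at least 99."""
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.repeat([0, 1], n // 2)
            sep = y * 4.0 + rng.normal(size=n)
            noise = rng.normal(size=n)
            w = relief_f(np.column_stack([sep, noise]), y, k_neighbors=5)
            wins += w[0] > w[1]
        assert wins >= 99

    def test_identical_copies_get_equal_weights(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = (x > 0).astype(int)
        w = relief_f(np.column_stack([x, x, x]), y, k_neighbors=3)
        assert np.allclose(w, w[0])

    def test_constant_feature_weight_zero(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = np.repeat([0, 1], 10)
        w = relief_f(X, y, k_neighbors=3)
        assert w[0] == 0.0

    def test_k_too_large_rejected(self):
        X = np.zeros((10, 2))
        y = np.repeat([0, 1], 5)
        with pytest.raises(ValueError):
            relief_f(X, y, k_neighbors=5)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = 18
        X = rng.normal(size=(n, 2))
        y = rng.integers(0, 3, size=n)
        while np.unique(y, return_counts=True)[1].min() < 4:
            y = rng.integers(0, 3, size=n)
        got = relief_f(X, y, k_neighbors=3)
        want = brute_force_relief(X, y, k=3)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_ranking_tie_break_by_index(self):
        assert rank_features(np.array([1.0, 2.0, 2.0, 0.5]), 2).tolist() == [1, 2]


class TestGridSearch:
    def test_single_point_grid(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 3))
        y = np.repeat([0, 1], 20)
        C, gamma, _ = grid_search_svm(
            X, y, SvmConfig(c_grid=(2.0,), gamma_grid=(0.7,))
        )
        assert (C, gamma) == (2.0, 0.7)

    def test_separable_blobs_reach_perfect_cv(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (30, 2)), rng.normal(5, 0.1, (30, 2))])
        y = np.repeat([0, 1], 30)
        _, _, acc = grid_search_svm(X, y, SvmConfig())
        assert acc == 1.0

    def test_permuted_labels_are_chance_level(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(120, 4))
        y = rng.permutation(np.repeat([0, 1], 60))
        _, _, acc = grid_search_svm(X, y, SvmConfig())
        assert acc == pytest.approx(0.5, abs=0.10)

    def test_class_smaller_than_folds_rejected(self):
        X = np.zeros((11, 2))
        y = np.array([0] * 8 + [1] * 3)
        with pytest.raises(ValueError):
            grid_search_svm(X, y, SvmConfig())


class TestBundle:
    def test_selected_feature_counts(self, bundle):
        assert len(bundle.axis_model.selected) == 10
        assert len(bundle.rotinv_model.selected) == 40

    def test_training_determinism(self, cohort):
        """Same cohort and seed twice: identical selections and CV scores."""
        recs = [s.recording for s in cohort.train[:4]]
        tracks = [s.track for s in cohort.train[:4]]
        cfg = SvmConfig(c_grid=(0.1, 1.0), gamma_grid=(0.5, 2.24), seed=5)
        b1 = train_bundle(recs, tracks, config=cfg)
        b2 = train_bundle(recs, tracks, config=cfg)
        assert b1.axis_model.selected.tolist() == b2.axis_model.selected.tolist()
        assert b1.rotinv_model.selected.tolist() == b2.rotinv_model.selected.tolist()
        assert b1.axis_model.cv_accuracy == b2.axis_model.cv_accuracy
        assert (b1.axis_model.C, b1.axis_model.gamma) == (
            b2.axis_model.C,
            b2.axis_model.gamma,
        )

    def test_missing_class_named_in_error(self, cohort):
        recs, tracks = [], []
        for s in cohort.train[:4]:
            recs.append(s.recording)
            tracks.append(
                wa.AnnotationTrack(
                    [iv for iv in s.track.intervals if iv[2] != "laying"]
                )
            )
        with pytest.raises(ValueError, match="LAYING"):
            train_bundle(recs, tracks)

    def test_all_zero_recording_predicts_valid_labels(self, bundle):
        rec = Recording(
            subject_id="zero",
            channels={c: np.zeros(200) for c in CHANNELS_3},
            sampling_rate_hz=25.0,
        )
        series = predict_windows(rec, bundle)
        assert len(series.raw_labels) == 4
        assert all(isinstance(l, wa.ActivityLabel) for l in series.raw_labels)

    def test_prediction_invariant_to_global_offset(self, upright_subjects, bundle):
        """A constant offset on all axes is absorbed by baseline alignment
        on the axis-dependent path."""
        rec = upright_subjects[0].recording
        shifted = rec.with_channels(
            {
                **rec.channels,
                **{
                    c: rec.channels[c] + 0.2
                    for c in CHANNELS_3
                },
            }
        )
        from wearact.orientation import ModelChoice

        a = predict_windows(rec, bundle, force_model=ModelChoice.AXIS_DEPENDENT)
        b = predict_windows(shifted, bundle, force_model=ModelChoice.AXIS_DEPENDENT)
        agree = np.mean([x == y for x, y in zip(a.raw_labels, b.raw_labels)])
        assert agree > 0.99

    def test_save_load_round_trip(self, bundle, tmp_path):
        path = tmp_path / "model.bundle"
        bundle.save(path)
        loaded = wa.ModelBundle.load(path)
        assert loaded.axis_model.selected.tolist() == bundle.axis_model.selected.tolist()
        assert loaded.manifest_digests == bundle.manifest_digests
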