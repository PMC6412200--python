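"""Feature manifests, primitives, reduction and scaling."""

import importlib.resources as resources

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import wearact as wa
from wearact.features import (
    AXIS_MANIFEST,
    AXIS_MANIFEST_LENGTH,
    ROTINV_MANIFEST,
    ROTINV_MANIFEST_LENGTH,
    FeaturePrimitive,
    apply_scaler,
    build_manifests,
    extract_matrix,
    fit_scaler,
    primitive_value,
    rotation_invariant_reduce,
    spectrum64,
)
from wearact.preprocess import compute_bundle

FS = 25.0


class TestManifests:
    def test_reference_lengths(self):
        assert len(AXIS_MANIFEST) == 254
        assert len(ROTINV_MANIFEST) == 90

    def test_rebuild_is_deterministic(self):
        a, r = build_manifests()
        assert a.to_yaml() == AXIS_MANIFEST.to_yaml()
        assert r.to_yaml() == ROTINV_MANIFEST.to_yaml()

    @pytest.mark.parametrize(
        "fname,manifest",
        [
            ("manifest_axis_dependent.yaml", AXIS_MANIFEST),
            ("manifest_rotation_invariant.yaml", ROTINV_MANIFEST),
        ],
    )
    def test_shipped_artifact_matches_code(self, fname, manifest):
        shipped = (resources.files("wearact") / "data" / fname).read_text()
        assert shipped == manifest.to_yaml()

    def test_all_sixteen_primitives_used(self):
        used = {e.primitive for e in AXIS_MANIFEST.entries}
        assert used == set(FeaturePrimitive)


class TestPrimitives:
    def test_mean_of_constant(self):
        assert primitive_value(FeaturePrimitive.MEAN, np.full(68, 0.5)) == 0.5

    def test_sma_of_constant_triaxial(self):
        ones = np.ones(68)
        assert primitive_value(FeaturePrimitive.SMA, ones, ones, ones) == 3.0

    def test_ar_yule_walker_oracle(self):
        """Order-4 fit on a long AR(1) realization recovers the coefficient."""
        rng = np.random.default_rng(5)
        n = 100_000
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = 0.5 * x[i - 1] + rng.normal()
        coefs = primitive_value(FeaturePrimitive.AR_COEF, x, order=4)
        assert coefs[0] == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("k", [3, 10, 25])
    def test_max_freq_ind_of_pure_sinusoid(self, k):
        # bin k of the zero-padded 128-point FFT is k*fs/128 Hz
        t = np.arange(68) / FS
        x = np.sin(2 * np.pi * (k * FS / 128) * t)
        assert primitive_value(FeaturePrimitive.MAX_FREQ_IND, x) == k
        spec = spectrum64(x)
        assert spec.shape == (1, 64)
        assert spec[0].argmax() == k

    def test_correlation_zero_variance_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            v = primitive_value(
                FeaturePrimitive.CORRELATION, np.ones(68), np.arange(68.0)
            )
        assert v == 0.0


@pytest.fixture(scope="module")
def windowed_features(single_recording):
    rec, _ = single_recording
    ws = wa.segment_windows(rec)
    bundle = compute_bundle(rec.acc(), rec.sampling_rate_hz)
    X = extract_matrix(bundle, ws.start_indices, ws.window_len, FS)
    return rec, ws, X


class TestExtraction:
    def test_axis_vector_length(self, windowed_features):
        _, _, X = windowed_features
        assert X.shape[1] == AXIS_MANIFEST_LENGTH

    def test_rotinv_vector_length(self, windowed_features):
        _, _, X = windowed_features
        assert rotation_invariant_reduce(X).shape[1] == ROTINV_MANIFEST_LENGTH

    def test_determinism(self, windowed_features):
        rec, ws, X = windowed_features
        bundle = compute_bundle(rec.acc(), rec.sampling_rate_hz)
        X2 = extract_matrix(bundle, ws.start_indices, ws.window_len, FS)
        np.testing.assert_array_equal(X, X2)


class TestReduction:
    def test_triplet_norm(self):
        X = np.zeros(254)
        entry = next(e for e in ROTINV_MANIFEST.entries if e.kind == "norm")
        X[list(entry.source_indices)] = [3.0, 4.0, 0.0]
        out = rotation_invariant_reduce(X)
        j = ROTINV_MANIFEST.entries.index(entry)
        assert out[j] == 5.0

    def test_wrong_layout_rejected(self):
        with pytest.raises(Exception):
            rotation_invariant_reduce(np.zeros(90))

    @staticmethod
    def invariant_indices():
        """Reduced features that are exactly rotation invariant: time-domain
        MEAN/STD norms, all quadratic (energy-scale) reductions, and the
        magnitude-signal pass-throughs."""
        time_signals = {"body_acc", "gravity_acc", "body_jerk"}
        idx = []
        for j, e in enumerate(ROTINV_MANIFEST.entries):
            src = AXIS_MANIFEST.entries[e.source_indices[0]]
            if e.kind == "sqrt_sum":
                idx.append(j)
            elif (
                e.kind == "norm"
                and src.signal in time_signals
                and src.primitive in (FeaturePrimitive.MEAN, FeaturePrimitive.STD)
            ):
                idx.append(j)
            elif e.kind == "pass" and src.signal.startswith("mag_"):
                idx.append(j)
        return idx

    def test_exact_invariance_under_rotation(self, single_recording):
        rec, _ = single_recording
        ws = wa.segment_windows(rec)
        X = wa.rotation_invariant_reduce(
            extract_matrix(
                compute_bundle(rec.acc(), FS), ws.start_indices, ws.window_len, FS
            )
        )
        idx = self.invariant_indices()
        rng = np.random.default_rng(11)
        for _ in range(5):
            R = wa.random_rotation(rng)
            rec2 = wa.apply_rotation(rec, R)
            X2 = wa.rotation_invariant_reduce(
                extract_matrix(
                    compute_bundle(rec2.acc(), FS), ws.start_indices, ws.window_len, FS
                )
            )
            rel = np.abs(X2[:, idx] - X[:, idx]) / (np.abs(X[:, idx]) + 1e-12)
            assert rel.max() < 1e-6

    def test_mean_std_norms_match_closed_form(self):
        """Reduced MEAN = ||mean vector||; reduced STD = sqrt(trace of cov)."""
        rng = np.random.default_rng(4)
        w = rng.normal(size=(68, 3)) * [1.0, 2.0, 0.5] + [0.3, -0.2, 0.9]
        R = Rotation.random(random_state=7).as_matrix()
        for data in (w, w @ R.T):
            mu = np.linalg.norm(data.mean(axis=0))
            sd = np.sqrt(data.var(axis=0).sum())
            np.testing.assert_allclose(mu, np.linalg.norm(w.mean(axis=0) @ R.T), rtol=1e-9)
            np.testing.assert_allclose(sd, np.sqrt(w.var(axis=0).sum()), rtol=1e-9)


class TestScaler:
    def test_closed_form_column(self):
        params = fit_scaler(np.array([[1.0], [2.0], [3.0]]))
        out = apply_scaler(np.array([[1.0], [2.0], [3.0]]), params)
        np.testing.assert_allclose(
            out[:, 0], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_constant_column_guarded(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
        params = fit_scaler(X)
        out = apply_scaler(X, params)
        assert np.all(out[:, 1] == 0.0)

    def test_fit_data_is_standardized(self):
        rng = np.random.default_rng(2)
        X = rng.normal(2.0, 5.0, size=(40, 6))
        out = apply_scaler(X, fit_scaler(X))
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)

    def test_affine_round_trip(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        params = fit_scaler(X)
        new = rng.normal(size=(5, 4))
        out = apply_scaler(new, params)
        back = out * np.where(params.std > 0, params.std, 1.0) + params.mean
        np.testing.assert_allclose(back, new, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        params = fit_scaler(np.zeros((3, 4)))
        with pytest.raises(ValueError):
            apply_scaler(np.zeros((2, 5)), params)
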