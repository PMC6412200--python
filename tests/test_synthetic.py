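"""Synthetic protocol recordings, injectors and cohorts."""

import numpy as np
import pytest
from sklearn.svm import LinearSVC

import wearact as wa
from wearact.core_io import ActivityLabel, CHANNELS_9
from wearact.synthetic import (
    InconsistencyInjector,
    SynthSubjectParams,
    apply_device_bias,
    apply_rotation,
    default_protocol_track,
    random_rotation,
    simulate_recording,
)


class TestSimulate:
    def test_protocol_duration(self, single_recording):
        rec, track = single_recording
        assert rec.n_samples == 6750  # (60+60+60+30+30+30) s at 25 Hz
        assert rec.duration_s == 270.0
        assert track.intervals[-1][1] == 270.0
        assert rec.n_channels == 9

    def test_static_magnitude_near_one_g(self, single_recording):
        rec, _ = single_recording
        # interior of the standing minute, clear of transitions
        seg = slice(10 * 25, 55 * 25)
        mag = np.linalg.norm(rec.acc()[seg], axis=1)
        assert abs(mag.mean() - 1.0) <= 3 * 0.03

    def test_same_seed_bit_identical(self):
        p = SynthSubjectParams(seed=42)
        r1, _ = simulate_recording(p)
        r2, _ = simulate_recording(p)
        for c in CHANNELS_9:
            np.testing.assert_array_equal(r1.channels[c], r2.channels[c])

    def test_gyroscope_active_only_during_locomotion(self, single_recording):
        rec, _ = single_recording
        gyr = np.column_stack([rec.channels[f"gyr_{a}"] for a in "xyz"])
        walking = slice(130 * 25, 175 * 25)
        standing = slice(10 * 25, 55 * 25)
        assert gyr[walking].std() > 5 * gyr[standing].std()


class TestRotation:
    def test_identity(self, single_recording):
        rec, _ = single_recording
        out = apply_rotation(rec, np.eye(3))
        for c in CHANNELS_9:
            np.testing.assert_array_equal(out.channels[c], rec.channels[c])

    def test_quarter_turn_about_z_maps_axes(self, single_recording):
        rec, _ = single_recording
        R = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out = apply_rotation(rec, R)
        np.testing.assert_allclose(
            out.channels["acc_x"], -rec.channels["acc_y"], atol=1e-12
        )

    def test_magnitude_preserved(self, single_recording):
        rec, _ = single_recording
        R = random_rotation(np.random.default_rng(0))
        out = apply_rotation(rec, R)
        np.testing.assert_allclose(
            np.linalg.norm(out.acc(), axis=1),
            np.linalg.norm(rec.acc(), axis=1),
            atol=1e-12,
        )

    def test_improper_matrix_rejected(self, single_recording):
        rec, _ = single_recording
        with pytest.raises(ValueError):
            apply_rotation(rec, np.diag([1.0, 1.0, -1.0]))

    def test_misplacement_moves_vertical_axis(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            R = random_rotation(rng)
            tilt = np.degrees(np.arccos(np.clip(R[0, 0], -1, 1)))
            assert tilt >= 30.0


class TestDeviceBias:
    def test_offset_shifts_baseline_exactly(self, single_recording):
        rec, _ = single_recording
        inj = InconsistencyInjector(baseline_offset=np.array([0.2, 0.0, 0.0]))
        out = apply_device_bias(rec, inj)
        b0 = wa.estimate_baseline(rec).values
        b1 = wa.estimate_baseline(out).values
        np.testing.assert_allclose(b1 - b0, [0.2, 0.0, 0.0], atol=1e-12)
        assert out.device_kind is wa.DeviceKind.WWS

    def test_neutral_injector_is_identity(self, single_recording):
        rec, _ = single_recording
        out = apply_device_bias(rec, InconsistencyInjector())
        np.testing.assert_array_equal(out.channels["acc_x"], rec.channels["acc_x"])

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            InconsistencyInjector(scale=np.array([1.0, 0.0, 1.0]))


class TestCohort:
    def test_counts_and_flags(self, cohort):
        assert len(cohort.train) == 8
        assert len(cohort.test) == 20
        assert sum(s.rotated for s in cohort.test) == 10
        assert sum(s.biased for s in cohort.test) == 2
        assert all(not s.rotated and not s.biased for s in cohort.train)

    def test_same_seed_identical(self):
        c1 = wa.make_cohort(2, 2, 0.5, 0.5, master_seed=99)
        c2 = wa.make_cohort(2, 2, 0.5, 0.5, master_seed=99)
        for s1, s2 in zip(c1.subjects, c2.subjects):
            np.testing.assert_array_equal(
                s1.recording.channels["acc_x"], s2.recording.channels["acc_x"]
            )

    def test_every_subject_has_all_classes(self, cohort):
        for s in cohort.subjects:
            ws = wa.segment_windows(s.recording, wa.build_labels(s.track))
            present = {l for l in ws.labels if l is not None}
            assert present == set(ActivityLabel)

    def test_static_vs_locomotion_linearly_separable(self, cohort):
        """Static-posture and locomotion windows separate in the
        (STD, ENERGY) plane of the body-acceleration magnitude."""
        from wearact.preprocess import compute_bundle

        s = cohort.train[0]
        ws = wa.segment_windows(s.recording, wa.build_labels(s.track))
        merged = wa.build_labels(s.track)
        bundle = compute_bundle(s.recording.acc(), 25.0)
        fs = s.recording.sampling_rate_hz
        feats, labels = [], []
        for i, lab in enumerate(ws.labels):
            if lab in (ActivityLabel.TRANSITION, None):
                continue
            t0, t1 = ws.start_indices[i] / fs, (ws.start_indices[i] + 68) / fs
            # pure windows only: fully inside one labelled interval
            if not any(a <= t0 and t1 <= b for a, b, l in merged.intervals if l == lab.value):
                continue
            w = bundle.mag_body_acc[
                ws.start_indices[i] : ws.start_indices[i] + ws.window_len
            ]
            feats.append([w.std(), np.mean(w**2)])
            labels.append(lab in (ActivityLabel.WALKING, ActivityLabel.STAIRS))
        clf = LinearSVC(C=100.0).fit(feats, labels)
        assert clf.score(feats, labels) == 1.0

    def test_default_protocol_track_layout(self):
        track = default_protocol_track()
        assert [iv[2] for iv in track.intervals] == [
            "standing", "sitting", "walking", "upstairs", "downstairs", "laying",
        ]
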