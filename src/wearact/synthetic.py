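"""Synthetic annotated IMU cohorts.

Emulates the supervised recording protocol — standing 1 min, sitting 1 min,
walking 1 min, stairs up/down 30 s each, laying 30 s — at 25 Hz with nine
channels, together with the two inconsistency phenomena the pipeline is
built to absorb: whole-recording sensor rotation (device misplacement) and
per-axis baseline offset/scale (device-generation differences).

The signal model is deliberately statistical, not biomechanical: static
postures are an oriented 1-g gravity vector plus noise, locomotion adds a
step-frequency sinusoid with harmonics on the vertical and anteroposterior
device directions, and every activity change is bridged by a 5-s smooth
orientation interpolation (the windows later annotated as transitions).
The gyroscope oscillates during locomotion and is near-silent otherwise;
the magnetometer is a fixed field vector carried through the body
orientation.  The pipeline consumes window statistics, and these are the
statistics the protocol data exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .core_io import (
    CHANNELS_9,
    DEFAULT_FS_HZ,
    AnnotationTrack,
    DeviceKind,
    Recording,
)

#: the recording protocol: (duration_s, raw label)
DEFAULT_PROTOCOL = (
    (60.0, "standing"),
    (60.0, "sitting"),
    (60.0, "walking"),
    (30.0, "upstairs"),
    (30.0, "downstairs"),
    (30.0, "laying"),
)
TRANSITION_S = 5.0
#: reference gravity direction in the device frame when worn upright (-X up)
G_REF = np.array([-1.0, 0.0, 0.0])
#: anteroposterior device direction when worn upright
AP_REF = np.array([0.0, 0.0, 1.0])
#: ambient magnetic field in the upright device frame (arbitrary units)
MAG_REF = np.array([0.25, 0.10, -0.40])

#: minimum rotation angle when emulating misplacement — a near-identity
#: draw is not a misplacement and has no meaningful routing ground truth
MIN_MISPLACEMENT_DEG = 30.0


@dataclass
class SynthSubjectParams:
    """Per-subject gait and noise parameters (units noted per field)."""

    step_freq_walk_hz: float = 1.7      # 1.4 - 2.0
    step_freq_stairs_hz: float = 1.1    # 0.9 - 1.4
    osc_amp_walk_g: float = 0.20        # 0.10 - 0.30
    osc_amp_stairs_g: float = 0.28      # 0.15 - 0.40
    noise_sigma_g: float = 0.03
    gyro_amp_dps: float = 45.0          # locomotion angular-rate amplitude
    gyro_noise_dps: float = 1.0
    mag_noise: float = 0.01
    sit_tilt_deg: float = 15.0          # recline of the trunk when seated
    lay_axis: str = "z"                 # device axis gravity falls on when laying
    lay_sign: float = 1.0
    seed: int = 0

    @classmethod
    def draw(cls, rng: np.random.Generator, seed: int) -> "SynthSubjectParams":
        walk_f = rng.uniform(1.4, 2.0)
        # stair cadence is a fraction of the subject's level-walking cadence
        stair_f = float(np.clip(walk_f * rng.uniform(0.60, 0.82), 0.9, 1.4))
        return cls(
            step_freq_walk_hz=walk_f,
            step_freq_stairs_hz=stair_f,
            osc_amp_walk_g=rng.uniform(0.10, 0.30),
            osc_amp_stairs_g=rng.uniform(0.15, 0.40),
            noise_sigma_g=0.03,
            gyro_amp_dps=rng.uniform(30.0, 60.0),
            sit_tilt_deg=rng.uniform(10.0, 20.0),
            # protocol laying is supine on a bed, device on the sternum:
            # gravity falls on +Z for every subject (plus per-activity jitter)
            lay_axis="z",
            lay_sign=1.0,
            seed=seed,
        )


@dataclass
class InconsistencyInjector:
    """Device-profile emulation: optional rotation, offset and scale."""

    rotation: Optional[np.ndarray] = None      # 3x3 proper rotation
    baseline_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.baseline_offset = np.asarray(self.baseline_offset, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if np.any(self.scale <= 0):
            raise ValueError("scale factors must be positive")
        if self.rotation is not None:
            _check_rotation(self.rotation)


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
        raise ValueError("rotation must be proper (determinant +1)")
    return R


def _activity_orientation(label: str, params: SynthSubjectParams,
                          rng: np.random.Generator) -> Rotation:
    """Device orientation (as rotation from the upright reference) per activity."""
    jitter = Rotation.from_rotvec(np.deg2rad(rng.uniform(-3, 3, size=3)))
    if label in ("standing", "walking", "upstairs", "downstairs"):
        base = Rotation.from_euler("y", rng.uniform(-5, 5), degrees=True)
    elif label == "sitting":
        base = Rotation.from_euler("y", params.sit_tilt_deg, degrees=True)
    elif label == "laying":
        # rotate the upright -X gravity onto +/-Y or +/-Z of the device
        axis = "z" if params.lay_axis == "y" else "y"
        angle = 90.0 * params.lay_sign
        base = Rotation.from_euler(axis, angle, degrees=True)
    else:
        raise ValueError(f"unknown protocol label {label!r}")
    return base * jitter


def default_protocol_track(protocol=DEFAULT_PROTOCOL) -> AnnotationTrack:
    intervals, t = [], 0.0
    for dur, label in protocol:
        intervals.append((t, t + dur, label))
        t += dur
    return AnnotationTrack(intervals)


def simulate_recording(
    params: SynthSubjectParams,
    protocol: Optional[AnnotationTrack] = None,
    fs: float = DEFAULT_FS_HZ,
    subject_id: str = "synth",
) -> tuple[Recording, AnnotationTrack]:
    """Simulate one 9-channel protocol recording; reproducible from seed."""
    track = protocol or default_protocol_track()
    rng = np.random.default_rng(params.seed)
    t_end = track.intervals[-1][1]
    n = int(round(t_end * fs))
    t = np.arange(n) / fs

    # orientation keyframes: hold each activity's orientation, slerp over
    # the first TRANSITION_S seconds of every new activity
    key_times, key_rots = [], []
    prev_rot: Optional[Rotation] = None
    for start, end, label in track.intervals:
        rot = _activity_orientation(label, params, rng)
        blend = min(TRANSITION_S, end - start)
        if prev_rot is None:
            key_times.append(start)
            key_rots.append(rot)
        else:
            key_times.append(start + blend)
            key_rots.append(rot)
        key_times.append(end)
        key_rots.append(rot)
        prev_rot = rot
    slerp = Slerp(key_times, Rotation.concatenate(key_rots))
    R = slerp(np.clip(t, key_times[0], key_times[-1]))  # (n,) rotations
    Rm = R.as_matrix()

    gravity = Rm @ G_REF                 # (n, 3) device-frame gravity, g units
    vertical = gravity / np.linalg.norm(gravity, axis=1, keepdims=True)
    antero = Rm @ AP_REF
    lateral = Rm @ np.array([0.0, 1.0, 0.0])

    def slow_noise(m: int, tau_s: float = 2.0) -> np.ndarray:
        """Unit-variance noise smoothed over ~tau_s (stride variability)."""
        w = max(int(tau_s * fs), 1)
        x = np.convolve(rng.normal(size=m + w), np.ones(w) / w, mode="valid")[:m]
        s = x.std()
        return x / s if s > 0 else x

    acc = gravity.copy()
    gyr = rng.normal(0.0, params.gyro_noise_dps, size=(n, 3))
    phase = rng.uniform(0, 2 * np.pi, size=4)
    for start, end, label in track.intervals:
        seg = (t >= start) & (t < end)
        m = int(seg.sum())
        if label in ("walking", "upstairs", "downstairs"):
            if label == "walking":
                f, amp = params.step_freq_walk_hz, params.osc_amp_walk_g
                harm = 0.30
            else:
                f, amp = params.step_freq_stairs_hz, params.osc_amp_stairs_g
                harm = 0.55
            # stride-to-stride variability: slow frequency and amplitude
            # modulation instead of a perfectly stationary oscillation
            f_inst = f * (1.0 + 0.06 * slow_noise(m))
            phi = 2 * np.pi * np.cumsum(f_inst) / fs
            env = 1.0 + 0.20 * slow_noise(m)
            a_v = env * (amp * np.sin(phi + phase[0]) + harm * amp * np.sin(2 * phi + phase[1]))
            a_a = env * 0.4 * amp * np.sin(phi + phase[2])
            # mediolateral sway alternates left/right once per stride,
            # i.e. at half the step frequency
            a_l = env * 0.3 * amp * np.sin(0.5 * phi + phase[3])
            acc[seg] += (
                vertical[seg] * a_v[:, None]
                + antero[seg] * a_a[:, None]
                + lateral[seg] * a_l[:, None]
            )
            g_osc = params.gyro_amp_dps * env * np.sin(phi + phase[3])
            gyr[seg, 1] += g_osc
            gyr[seg, 2] += 0.5 * g_osc
        else:
            # postural micro-motion: quiet standing sways constantly,
            # sitting less, lying hardly at all (breathing only)
            sway_amp = {"standing": 0.025, "sitting": 0.012, "laying": 0.004}[label]
            sway = np.column_stack([slow_noise(m, tau_s=1.0) for _ in range(3)])
            acc[seg] += sway_amp * sway
        # posture-change lurch: a slow movement burst (and trunk angular
        # rate) spanning the orientation change at the activity start
        blend = min(TRANSITION_S, end - start)
        tr = seg & (t < start + blend)
        k = int(tr.sum())
        if k and start > 0:
            # one slow swing (~0.4 Hz): a posture change is a single
            # movement, spectrally well below the 0.9-2 Hz gait band
            pulse = np.sin(np.pi * np.arange(k) / k)
            burst = 0.25 * pulse * np.sin(2 * np.pi * 0.4 * (t[tr] - start) + phase[0])
            acc[tr] += vertical[tr] * burst[:, None] + 0.5 * antero[tr] * burst[:, None]
            gyr[tr, 1] += 25.0 * pulse * np.sin(2 * np.pi * 0.4 * (t[tr] - start))
    acc += rng.normal(0.0, params.noise_sigma_g, size=(n, 3))

    mag = Rm @ MAG_REF + rng.normal(0.0, params.mag_noise, size=(n, 3))

    channels = dict(zip(CHANNELS_9, np.column_stack([acc, gyr, mag]).T))
    rec = Recording(
        subject_id=subject_id,
        channels=channels,
        sampling_rate_hz=fs,
        device_kind=DeviceKind.SYNTH,
    )
    return rec, track


def apply_rotation(rec: Recording, R: np.ndarray) -> Recording:
    """Left-multiply every sensor triplet by a proper rotation (active)."""
    R = _check_rotation(R)
    channels = dict(rec.channels)
    for base in ("acc", "gyr", "mag"):
        names = [f"{base}_{ax}" for ax in "xyz"]
        if not all(nm in channels for nm in names):
            continue
        tri = np.column_stack([channels[nm] for nm in names])
        rotated = tri @ R.T
        for j, nm in enumerate(names):
            channels[nm] = rotated[:, j]
    return rec.with_channels(channels)


def apply_device_bias(rec: Recording, inj: InconsistencyInjector) -> Recording:
    """Per-axis affine distortion of the accelerometer; re-tagged WWS."""
    channels = dict(rec.channels)
    for i, ax in enumerate("xyz"):
        nm = f"acc_{ax}"
        channels[nm] = inj.scale[i] * channels[nm] + inj.baseline_offset[i]
    out = rec.with_channels(channels, device_kind=DeviceKind.WWS)
    if inj.rotation is not None:
        out = apply_rotation(out, inj.rotation)
    return out


def random_rotation(
    rng: np.random.Generator, jitter_deg: float = 10.0
) -> np.ndarray:
    """A random gross-misplacement rotation.

    A permanently worn garment cannot sit at an arbitrary small angle; a
    misplacement means it has slipped or been donned sideways or facing the
    wrong way.  Draws are rotations that map the vertical (-X) axis onto a
    lateral or anteroposterior signed axis (+/-Y or +/-Z), composed with an
    arbitrary spin about the vertical and a small jitter of up to
    ``jitter_deg`` for imperfect wear.  (A full upside-down donning is
    blocked by the garment's cut and is not part of the model.)
    """
    targets = {
        "+y": ("z", 90.0),    # sideways
        "-y": ("z", -90.0),
        "+z": ("y", -90.0),   # facing up/down
        "-z": ("y", 90.0),
    }
    axis, angle = targets[rng.choice(sorted(targets))]
    base = Rotation.from_euler(axis, angle, degrees=True)
    spin = Rotation.from_euler("x", rng.uniform(0.0, 360.0), degrees=True)
    jitter = Rotation.from_rotvec(np.deg2rad(rng.uniform(-jitter_deg, jitter_deg, size=3)))
    return (jitter * base * spin).as_matrix()


@dataclass
class CohortSubject:
    recording: Recording
    track: AnnotationTrack
    params: SynthSubjectParams
    rotated: bool = False
    rotation: Optional[np.ndarray] = None
    biased: bool = False
    injector: Optional[InconsistencyInjector] = None


@dataclass
class Cohort:
    train: list[CohortSubject]
    test: list[CohortSubject]

    @property
    def subjects(self) -> list[CohortSubject]:
        return self.train + self.test


def make_cohort(
    n_train: int = 8,
    n_test: int = 12,
    fraction_rotated: float = 0.5,
    fraction_wws: float = 0.2,
    master_seed: int = 0,
) -> Cohort:
    """Draw a reproducible cohort.

    Training subjects are always upright with the reference device profile;
    among test subjects the first ``round(fraction_rotated * n_test)`` are
    rotated and the next ``round(fraction_wws * n_test)`` carry a WWS-style
    per-axis baseline offset.  Injector ground truth is retained.
    """
    if n_train < 2:
        raise ValueError("need >= 2 training subjects")
    rng = np.random.default_rng(master_seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_train + n_test)

    def make_subject(i: int, role: str) -> CohortSubject:
        sub_rng = np.random.default_rng(int(seeds[i]))
        params = SynthSubjectParams.draw(sub_rng, seed=int(seeds[i]))
        rec, track = simulate_recording(params, subject_id=f"{role}{i:02d}")
        return CohortSubject(recording=rec, track=track, params=params)

    train = [make_subject(i, "train") for i in range(n_train)]
    test = [make_subject(n_train + i, "test") for i in range(n_test)]

    n_rot = int(round(fraction_rotated * n_test))
    n_wws = int(round(fraction_wws * n_test))
    inj_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    for subj in test[:n_rot]:
        R = random_rotation(inj_rng)
        subj.recording = apply_rotation(subj.recording, R)
        subj.rotated, subj.rotation = True, R
    for subj in test[n_rot : n_rot + n_wws]:
        inj = InconsistencyInjector(
            baseline_offset=inj_rng.uniform(0.1, 0.3, size=3)
            * inj_rng.choice([-1.0, 1.0], size=3)
        )
        subj.recording = apply_device_bias(subj.recording, inj)
        subj.biased, subj.injector = True, inj
    return Cohort(train=train, test=test)
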