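"""Gravity/body separation, jerk and magnitude signals.

The raw tri-axial acceleration mixes the quasi-static gravity component
(which encodes posture) with the dynamic body component (which encodes
movement).  A zero-phase low-pass at 0.3 Hz splits the two; the body jerk
(time derivative of body acceleration) and the Euclidean magnitudes of the
tri-axial signals complete the bundle the feature stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

GRAVITY_CUTOFF_HZ = 0.3
_FILTER_ORDER = 3


@dataclass
class SignalBundle:
    """Derived signals for one recording; tri-axial arrays are (n, 3)."""

    body_acc: np.ndarray
    gravity_acc: np.ndarray
    body_jerk: np.ndarray
    mag_body_acc: np.ndarray
    mag_gravity_acc: np.ndarray
    mag_body_jerk: np.ndarray

    def signals(self) -> dict[str, np.ndarray]:
        return {
            "body_acc": self.body_acc,
            "gravity_acc": self.gravity_acc,
            "body_jerk": self.body_jerk,
            "mag_body_acc": self.mag_body_acc,
            "mag_gravity_acc": self.mag_gravity_acc,
            "mag_body_jerk": self.mag_body_jerk,
        }


def denoise(series: np.ndarray) -> np.ndarray:
    """Width-3 median filter with replicated edges; removes impulse spikes."""
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        if len(x) < 3:
            return x.copy()
        padded = np.concatenate([x[:1], x, x[-1:]])
        stacked = np.stack([padded[:-2], padded[1:-1], padded[2:]])
        return np.median(stacked, axis=0)
    return np.column_stack([denoise(x[:, j]) for j in range(x.shape[1])])


def split_gravity(
    acc: np.ndarray, fs: float, cutoff_hz: float = GRAVITY_CUTOFF_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Separate gravity (low-pass) and body (residual) acceleration.

    Zero-phase 3rd-order Butterworth, applied forward-backward so postures
    stay aligned in time.  The decomposition is exact: gravity + body
    reconstructs the input.
    """
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist {fs / 2} Hz")
    acc = np.asarray(acc, dtype=float)
    sos = sp_signal.butter(_FILTER_ORDER, cutoff_hz, btype="low", fs=fs, output="sos")
    gravity = sp_signal.sosfiltfilt(sos, acc, axis=0)
    body = acc - gravity
    return gravity, body


def jerk(series3: np.ndarray, fs: float) -> np.ndarray:
    """First difference scaled by fs; first value repeated to keep length."""
    x = np.asarray(series3, dtype=float)
    d = np.diff(x, axis=0) * fs
    return np.concatenate([d[:1], d], axis=0)


def magnitude(series3: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a tri-axial signal."""
    return np.linalg.norm(np.asarray(series3, dtype=float), axis=-1)


def compute_bundle(
    acc: np.ndarray,
    fs: float,
    cutoff_hz: float = GRAVITY_CUTOFF_HZ,
    *,
    median_denoise: bool = False,
) -> SignalBundle:
    """Full preprocessing chain from raw tri-axial acceleration.

    The impulse-removing median filter is off by default: it is a per-axis
    order statistic, so it would break the exact rotation commutativity the
    rotation-invariant feature path relies on.  Enable it for recordings
    with genuine telemetry spikes.
    """
    acc = np.asarray(acc, dtype=float)
    if median_denoise:
        acc = denoise(acc)
    gravity, body = split_gravity(acc, fs, cutoff_hz)
    body_jerk = jerk(body, fs)
    return SignalBundle(
        body_acc=body,
        gravity_acc=gravity,
        body_jerk=body_jerk,
        mag_body_acc=magnitude(body),
        mag_gravity_acc=magnitude(gravity),
        mag_body_jerk=magnitude(body_jerk),
    )
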