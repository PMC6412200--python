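"""Cross-device baseline correction.

The two garment generations (WWS and WWBS) report accelerations on shifted
scales.  Each axis's baseline is the mean of its quiet segments — time
segments whose standard deviation falls below the 40th percentile of
segment standard deviations, which in the protocol are the static postures
— and every recording is mapped into the reference measurement space by a
per-axis shift onto the reference baseline.

The 0.4 quantile keeps essentially every static segment, so the posture
composition of the baseline (and hence the baseline itself) is stable
across subjects; a very low quantile would instead select a noise-driven
subsample of the static segments, whose standing/sitting/laying mix — and
with it the baseline — fluctuates from recording to recording.

The correction is shift-only by default (it preserves every central moment
of order >= 2); a per-axis scale factor derived from quiet-segment spreads
can be enabled for devices that also rescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_io import CHANNELS_3, Recording

SEGMENT_LEN_S = 2.0
STD_QUANTILE = 0.4


@dataclass
class BaselineVector:
    """Per-axis accelerometer baseline, same units as the channels."""

    values: np.ndarray  # (3,) for acc_x, acc_y, acc_z

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3,) or not np.all(np.isfinite(self.values)):
            raise ValueError("baseline must be 3 finite per-axis values")


def _quiet_segment_stats(
    x: np.ndarray, seg_len: int, quantile: float
) -> tuple[float, float]:
    """(mean, std) pooled over the low-std segments of one axis."""
    n_seg = len(x) // seg_len
    if n_seg < 1:
        warnings.warn(
            "recording shorter than one baseline segment; using whole-series mean",
            stacklevel=3,
        )
        return float(x.mean()), float(x.std())
    segs = x[: n_seg * seg_len].reshape(n_seg, seg_len)
    stds = segs.std(axis=1)
    keep = stds <= np.quantile(stds, quantile)
    return float(segs[keep].mean(axis=1).mean()), float(stds[keep].mean())


def estimate_baseline(
    rec: Recording,
    segment_len_s: float = SEGMENT_LEN_S,
    std_quantile: float = STD_QUANTILE,
) -> BaselineVector:
    """Per-axis mean of the quietest non-overlapping segments."""
    seg_len = max(int(round(segment_len_s * rec.sampling_rate_hz)), 1)
    means = [
        _quiet_segment_stats(rec.channels[c], seg_len, std_quantile)[0]
        for c in CHANNELS_3
    ]
    return BaselineVector(np.array(means))


def estimate_quiet_scale(
    rec: Recording,
    segment_len_s: float = SEGMENT_LEN_S,
    std_quantile: float = STD_QUANTILE,
) -> np.ndarray:
    """Per-axis spread of the quietest segments (basis for optional rescaling)."""
    seg_len = max(int(round(segment_len_s * rec.sampling_rate_hz)), 1)
    return np.array(
        [
            _quiet_segment_stats(rec.channels[c], seg_len, std_quantile)[1]
            for c in CHANNELS_3
        ]
    )


def align_baseline(
    rec: Recording,
    target: BaselineVector,
    own: Optional[BaselineVector] = None,
    *,
    rescale: bool = False,
    target_scale: Optional[np.ndarray] = None,
) -> Recording:
    """Shift accelerometer axes so the recording's baseline equals ``target``.

    ``output = input - own_baseline + target_baseline`` per axis; ``own`` is
    estimated from the recording when not supplied.  With ``rescale`` the
    centred signal is additionally multiplied by the ratio of reference to
    own quiet-segment spreads (off by default: the documented correction is
    a pure shift).
    """
    if own is None:
        own = estimate_baseline(rec)
    channels = dict(rec.channels)
    scale = np.ones(3)
    if rescale:
        own_scale = estimate_quiet_scale(rec)
        ref_scale = np.asarray(target_scale, dtype=float)
        ok = own_scale > 0
        scale[ok] = ref_scale[ok] / own_scale[ok]
    for i, c in enumerate(CHANNELS_3):
        channels[c] = (rec.channels[c] - own.values[i]) * scale[i] + target.values[i]
    return rec.with_channels(channels)
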