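"""Data model, file I/O, windowing and label construction.

Recordings are multichannel inertial streams sampled at a constant nominal
rate (25 Hz for the chest-worn garments this package targets).  Annotations
are interval tracks produced by an instructor with a stopwatch; they are
mapped onto the five-class activity scheme (sit/stand, laying, walking,
stairs, transition) and then onto fixed-width sliding windows by majority
vote.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Canonical channel order.  Accelerometer channels are mandatory;
#: gyroscope and magnetometer are present only in 9-channel mode.
CHANNELS_9 = (
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
)
CHANNELS_3 = CHANNELS_9[:3]

DEFAULT_FS_HZ = 25.0
#: Window geometry: 68 samples at 25 Hz = 2.72 s, 50% overlap (hop 34).
WINDOW_LEN = 68
WINDOW_OVERLAP = 0.5
#: Leading seconds of every annotated activity re-labelled as transition.
TRANSITION_S = 5.0


class DeviceKind(str, Enum):
    WWS = "WWS"       # older wellness garment generation
    WWBS = "WWBS"     # newer body-area-network garment generation
    SYNTH = "SYNTH"   # synthetic cohort generator


class ActivityLabel(str, Enum):
    """The five merged activity classes."""

    SIT_STAND = "SIT_STAND"
    LAYING = "LAYING"
    WALKING = "WALKING"
    STAIRS = "STAIRS"
    TRANSITION = "TRANSITION"


#: Raw annotation vocabulary -> merged class.
RAW_LABEL_MAP = {
    "standing": ActivityLabel.SIT_STAND,
    "sitting": ActivityLabel.SIT_STAND,
    "walking": ActivityLabel.WALKING,
    "upstairs": ActivityLabel.STAIRS,
    "downstairs": ActivityLabel.STAIRS,
    "laying": ActivityLabel.LAYING,
}


class MalformedInputError(ValueError):
    """Raised on structurally invalid input files."""


class SchemaError(ValueError):
    """Raised when channel names do not match the declared schema."""


class LabelError(ValueError):
    """Raised on an unknown raw annotation label."""


class EmptySeriesError(ValueError):
    """Raised when a recording is too short to yield a single window."""


@dataclass
class Recording:
    """A subject's multichannel stream at a constant sampling rate.

    ``channels`` maps canonical channel names to equal-length float arrays.
    """

    subject_id: str
    channels: dict[str, np.ndarray]
    sampling_rate_hz: float = DEFAULT_FS_HZ
    device_kind: DeviceKind = DeviceKind.SYNTH
    t0: float = 0.0

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise MalformedInputError("channel series have unequal lengths")
        if next(iter(lengths)) < 1:
            raise MalformedInputError("empty recording")
        for name in CHANNELS_3:
            if name not in self.channels:
                raise SchemaError(f"missing required channel {name!r}")
        for name in self.channels:
            if name not in CHANNELS_9:
                raise SchemaError(f"unknown channel name {name!r}")
        gyr_mag = [c for c in CHANNELS_9[3:] if c in self.channels]
        if gyr_mag and len(gyr_mag) != 6:
            raise SchemaError(
                "gyroscope/magnetometer channels must be all present (9-channel"
                f" mode) or all absent; got {gyr_mag}"
            )
        # canonical order, float64 contiguous
        self.channels = {
            name: np.ascontiguousarray(self.channels[name], dtype=float)
            for name in CHANNELS_9
            if name in self.channels
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        """Sample timestamps ``t0 + i / fs``."""
        return self.t0 + np.arange(self.n_samples) / self.sampling_rate_hz

    def acc(self) -> np.ndarray:
        """Accelerometer block, shape (n, 3)."""
        return np.column_stack([self.channels[c] for c in CHANNELS_3])

    def matrix(self) -> np.ndarray:
        """All channels in canonical order, shape (n, n_channels)."""
        return np.column_stack(list(self.channels.values()))

    def with_channels(self, channels: dict[str, np.ndarray], **kw) -> "Recording":
        return replace(self, channels=channels, **kw)


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping labelled intervals in seconds."""

    intervals: list[tuple[float, float, str]]

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for start, end, _ in self.intervals:
            if not start < end:
                raise MalformedInputError(f"interval ({start}, {end}) is empty")
            if start < prev_end:
                raise MalformedInputError("intervals overlap or are unsorted")
            prev_end = end

    def label_at(self, t: float) -> Optional[str]:
        """Label covering time ``t`` (start-inclusive, end-exclusive)."""
        for start, end, label in self.intervals:
            if start <= t < end:
                return label
        return None


@dataclass
class WindowSeries:
    """Fixed-width sliding windows cut from a recording."""

    window_len: int
    overlap_fraction: float
    start_indices: np.ndarray                  # (n_windows,)
    data: np.ndarray                           # (n_windows, window_len, n_channels)
    labels: Optional[list[ActivityLabel]]      # None when unannotated
    sampling_rate_hz: float
    channel_names: tuple[str, ...]

    @property
    def hop(self) -> int:
        return int(round(self.window_len * (1.0 - self.overlap_fraction)))

    @property
    def n_windows(self) -> int:
        return len(self.start_indices)

    def start_times_s(self) -> np.ndarray:
        return self.start_indices / self.sampling_rate_hz


def read_recording(
    path,
    schema: Sequence[str] = CHANNELS_3,
    *,
    subject_id: str = "",
    sampling_rate_hz: float = DEFAULT_FS_HZ,
    device_kind: DeviceKind = DeviceKind.SYNTH,
) -> Recording:
    """Read a delimited-text recording with one column per channel.

    An optional leading ``time_s`` column is used only to sanity-check the
    sampling grid; samples are indexed by row otherwise.
    """
    for name in schema:
        if name not in CHANNELS_9:
            raise SchemaError(f"unknown channel name {name!r} in schema")
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise MalformedInputError(str(exc)) from None
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(float)
        gaps = np.diff(t)
        if len(gaps) and np.any(gaps > 2.0 / sampling_rate_hz):
            warnings.warn(
                "timestamp gap exceeds 2/fs; recording treated as contiguous",
                stacklevel=2,
            )
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"file lacks declared channels {missing}")
    if df[list(schema)].isna().any().any():
        raise MalformedInputError("unequal column lengths (NaN padding found)")
    channels = {c: df[c].to_numpy(float) for c in schema}
    return Recording(
        subject_id=subject_id or str(path),
        channels=channels,
        sampling_rate_hz=sampling_rate_hz,
        device_kind=device_kind,
    )


def write_recording(rec: Recording, path) -> None:
    """Write a recording as comma-separated text with a header row."""
    df = pd.DataFrame({"time_s": rec.times(), **rec.channels})
    df.to_csv(path, index=False)


def read_annotations(path) -> AnnotationTrack:
    """Read an interval annotation file with columns start_s,end_s,label."""
    df = pd.read_csv(path)
    need = {"start_s", "end_s", "label"}
    if not need.issubset(df.columns):
        raise MalformedInputError(f"annotation file needs columns {sorted(need)}")
    return AnnotationTrack(
        [(float(r.start_s), float(r.end_s), str(r.label)) for r in df.itertuples()]
    )


def write_annotations(track: AnnotationTrack, path) -> None:
    pd.DataFrame(track.intervals, columns=["start_s", "end_s", "label"]).to_csv(
        path, index=False
    )


def build_labels(track: AnnotationTrack, transition_s: float = TRANSITION_S) -> AnnotationTrack:
    """Map raw labels to the merged five-class scheme.

    Sitting and standing merge into SIT_STAND, upstairs/downstairs into
    STAIRS, and the leading ``transition_s`` seconds of every interval are
    re-labelled TRANSITION (an interval shorter than that becomes entirely
    TRANSITION).
    """
    out: list[tuple[float, float, str]] = []
    for start, end, raw in track.intervals:
        key = raw.strip().lower()
        if key in {a.value.lower() for a in ActivityLabel}:
            mapped = ActivityLabel(key.upper())
        elif key in RAW_LABEL_MAP:
            mapped = RAW_LABEL_MAP[key]
        else:
            raise LabelError(f"unknown raw label {raw!r}")
        cut = min(start + transition_s, end)
        if cut > start:
            out.append((start, cut, ActivityLabel.TRANSITION.value))
        if end > cut:
            out.append((cut, end, mapped.value))
    return AnnotationTrack(out)


def _majority_label(
    track: AnnotationTrack, t_start: float, t_end: float, fs: float
) -> Optional[ActivityLabel]:
    """Majority label of the samples in [t_start, t_end); ties go to the
    chronologically earlier interval's label."""
    n = int(round((t_end - t_start) * fs))
    times = t_start + np.arange(n) / fs
    counts: dict[str, int] = {}
    first_seen: dict[str, int] = {}
    for i, t in enumerate(times):
        lab = track.label_at(t)
        if lab is None:
            continue
        counts[lab] = counts.get(lab, 0) + 1
        first_seen.setdefault(lab, i)
    if not counts:
        return None
    best = max(counts, key=lambda k: (counts[k], -first_seen[k]))
    return ActivityLabel(best)


def segment_windows(
    rec: Recording,
    track: Optional[AnnotationTrack] = None,
    window_len: int = WINDOW_LEN,
    overlap: float = WINDOW_OVERLAP,
) -> WindowSeries:
    """Cut fixed-width sliding windows; trailing partial window dropped.

    With ``track`` given (already passed through :func:`build_labels`), each
    window takes the majority label of its samples.
    """
    n = rec.n_samples
    if n < window_len:
        raise EmptySeriesError(
            f"recording has {n} samples, shorter than window_len={window_len}"
        )
    hop = int(round(window_len * (1.0 - overlap)))
    starts = np.arange(0, n - window_len + 1, hop)
    mat = rec.matrix()
    data = np.stack([mat[s : s + window_len] for s in starts])
    labels = None
    if track is not None:
        fs = rec.sampling_rate_hz
        labels = [
            _majority_label(track, rec.t0 + s / fs, rec.t0 + (s + window_len) / fs, fs)
            for s in starts
        ]
    return WindowSeries(
        window_len=window_len,
        overlap_fraction=overlap,
        start_indices=starts,
        data=data,
        labels=labels,
        sampling_rate_hz=rec.sampling_rate_hz,
        channel_names=tuple(rec.channels),
    )
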