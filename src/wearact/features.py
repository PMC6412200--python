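"""Windowed statistical features and the two reference manifests.

Two fixed feature recipes are shipped:

* ``AXIS_DEP`` — 254 features over the derived signal bundle (body, gravity
  and jerk accelerations, their magnitudes, and 64-bin spectra of the body
  signals) using 16 primitives.  Used when the device orientation matches
  the training reference.
* ``ROT_INV`` — 90 features obtained by collapsing every per-axis feature
  triplet (fX, fY, fZ) to the magnitude of the corresponding 3-D vector,
  passing magnitude-signal features through unchanged and dropping per-pair
  correlations.  Used when the device appears mis-oriented.

Primitives that are quadratic in the signal (ENERGY, BANDS_ENERGY) collapse
via sqrt(fX + fY + fZ) — the magnitude of the underlying amplitude vector —
so that the reduced value is exactly rotation invariant; linear-scale
primitives collapse via the Euclidean norm of the triplet.

The composition (the paper-level recipe fixes only the totals):

==============  ====================================================  =====
signal          primitives                                            count
==============  ====================================================  =====
body_acc        8 stats x3 axes, AR(4) x3, SMA, 3 correlations          40
gravity_acc     8 stats x3 axes, AR(4) x3, SMA                          37
body_jerk       8 stats x3 axes, AR(4) x3, SMA, 3 correlations          40
mag_*           MEAN, STD, ENERGY each (3 signals)                       9
f_body_acc      12 stats x3 axes, SMA, 3 corr., 8 bands x3 axes          64
f_body_jerk     same                                                     64
==============  ====================================================  =====

Total 254; triplet reduction yields 13+13+13+9+21+21 = 90.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import yaml
from scipy import stats as sp_stats

from .preprocess import SignalBundle

N_FFT = 128          # zero-padded FFT length: 64 one-sided bins
N_SPECTRUM_BINS = 64
AR_ORDER = 4
#: 8 contiguous bands over the 64-bin spectrum, finer at low frequencies so
#: the postural (<0.8 Hz), stairs (~0.9-1.4 Hz) and walking (~1.4-2 Hz)
#: fundamentals and their first harmonics fall into distinct bands
#: (bin width is fs/128 ~ 0.195 Hz at 25 Hz sampling).
BAND_EDGES = ((0, 4), (4, 8), (8, 12), (12, 16), (16, 24), (24, 32), (32, 48), (48, 64))

AXIS_NAMES = ("x", "y", "z")
PAIR_NAMES = (("x", "y"), ("x", "z"), ("y", "z"))

AXIS_MANIFEST_LENGTH = 254
ROTINV_MANIFEST_LENGTH = 90


class FeaturePrimitive(str, Enum):
    MEAN = "MEAN"
    STD = "STD"
    MAD = "MAD"
    MAX = "MAX"
    MIN = "MIN"
    SMA = "SMA"
    ENERGY = "ENERGY"
    IQR = "IQR"
    ENTROPY = "ENTROPY"
    AR_COEF = "AR_COEF"
    CORRELATION = "CORRELATION"
    MAX_FREQ_IND = "MAX_FREQ_IND"
    MEAN_FREQ = "MEAN_FREQ"
    SKEWNESS_F = "SKEWNESS_F"
    KURTOSIS_F = "KURTOSIS_F"
    BANDS_ENERGY = "BANDS_ENERGY"


#: primitives quadratic in the signal; their triplets collapse via sqrt-sum
_QUADRATIC = {FeaturePrimitive.ENERGY, FeaturePrimitive.BANDS_ENERGY}

_TIME_STATS = (
    FeaturePrimitive.MEAN,
    FeaturePrimitive.STD,
    FeaturePrimitive.MAD,
    FeaturePrimitive.MAX,
    FeaturePrimitive.MIN,
    FeaturePrimitive.ENERGY,
    FeaturePrimitive.IQR,
    FeaturePrimitive.ENTROPY,
)
_FREQ_STATS = _TIME_STATS + (
    FeaturePrimitive.MAX_FREQ_IND,
    FeaturePrimitive.MEAN_FREQ,
    FeaturePrimitive.SKEWNESS_F,
    FeaturePrimitive.KURTOSIS_F,
)
_MAG_STATS = (
    FeaturePrimitive.MEAN,
    FeaturePrimitive.STD,
    FeaturePrimitive.ENERGY,
)

TRIAXIAL_TIME_SIGNALS = ("body_acc", "gravity_acc", "body_jerk")
MAGNITUDE_SIGNALS = ("mag_body_acc", "mag_gravity_acc", "mag_body_jerk")
TRIAXIAL_FREQ_SIGNALS = ("f_body_acc", "f_body_jerk")
#: frequency-domain signals are spectra of these time signals
FREQ_SOURCE = {"f_body_acc": "body_acc", "f_body_jerk": "body_jerk"}
#: signals without per-axis correlation features
_NO_CORRELATION = {"gravity_acc"}


class ManifestError(ValueError):
    """Raised when a manifest does not match the data it is applied to."""


@dataclass(frozen=True)
class FeatureEntry:
    """One scalar output of the axis-dependent manifest."""

    signal: str
    primitive: FeaturePrimitive
    axis: Optional[int] = None                 # 0/1/2 for tri-axial entries
    pair: Optional[tuple[int, int]] = None     # correlation axis pair
    order: Optional[int] = None                # AR coefficient index
    band: Optional[int] = None                 # band index for BANDS_ENERGY
    name: str = ""
    group: Optional[str] = None                # triplet key; None for scalars
    role: str = "scalar"                       # "triplet" | "scalar" | "corr"


@dataclass(frozen=True)
class ReducedEntry:
    """One scalar output of the rotation-invariant manifest."""

    name: str
    source_indices: tuple[int, ...]            # indices into the axis layout
    kind: str                                  # "norm" | "sqrt_sum" | "pass"


@dataclass
class FeatureManifest:
    name: str
    entries: list                              # FeatureEntry or ReducedEntry

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def feature_names(self) -> list[str]:
        return [e.name for e in self.entries]

    def to_yaml(self) -> str:
        rows = []
        for e in self.entries:
            if isinstance(e, FeatureEntry):
                row = {"name": e.name, "signal": e.signal, "primitive": e.primitive.value}
                if e.axis is not None:
                    row["axis"] = AXIS_NAMES[e.axis]
                if e.pair is not None:
                    row["pair"] = "".join(AXIS_NAMES[i] for i in e.pair)
                if e.order is not None:
                    row["order"] = e.order
                if e.band is not None:
                    row["band"] = list(BAND_EDGES[e.band])
            else:
                row = {
                    "name": e.name,
                    "reduce": e.kind,
                    "sources": list(e.source_indices),
                }
            rows.append(row)
        return yaml.safe_dump(
            {"manifest": self.name, "length": len(self), "entries": rows},
            sort_keys=False,
        )

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _axis_entries() -> list[FeatureEntry]:
    entries: list[FeatureEntry] = []

    def triplet(signal, prim, *, order=None, band=None):
        tag = prim.value.lower()
        if order is not None:
            tag = f"ar{order}"
        if band is not None:
            tag = f"band{band}"
        for ax in range(3):
            entries.append(
                FeatureEntry(
                    signal=signal,
                    primitive=prim,
                    axis=ax,
                    order=order,
                    band=band,
                    name=f"{signal}_{tag}_{AXIS_NAMES[ax]}",
                    group=f"{signal}_{tag}",
                    role="triplet",
                )
            )

    for sig in TRIAXIAL_TIME_SIGNALS:
        for prim in _TIME_STATS:
            triplet(sig, prim)
        for k in range(AR_ORDER):
            triplet(sig, FeaturePrimitive.AR_COEF, order=k)
        entries.append(
            FeatureEntry(signal=sig, primitive=FeaturePrimitive.SMA, name=f"{sig}_sma")
        )
        if sig not in _NO_CORRELATION:
            for i, j in ((0, 1), (0, 2), (1, 2)):
                entries.append(
                    FeatureEntry(
                        signal=sig,
                        primitive=FeaturePrimitive.CORRELATION,
                        pair=(i, j),
                        name=f"{sig}_corr_{AXIS_NAMES[i]}{AXIS_NAMES[j]}",
                        role="corr",
                    )
                )

    for sig in MAGNITUDE_SIGNALS:
        for prim in _MAG_STATS:
            entries.append(
                FeatureEntry(
                    signal=sig, primitive=prim, name=f"{sig}_{prim.value.lower()}"
                )
            )

    for sig in TRIAXIAL_FREQ_SIGNALS:
        for prim in _FREQ_STATS:
            triplet(sig, prim)
        entries.append(
            FeatureEntry(signal=sig, primitive=FeaturePrimitive.SMA, name=f"{sig}_sma")
        )
        for i, j in ((0, 1), (0, 2), (1, 2)):
            entries.append(
                FeatureEntry(
                    signal=sig,
                    primitive=FeaturePrimitive.CORRELATION,
                    pair=(i, j),
                    name=f"{sig}_corr_{AXIS_NAMES[i]}{AXIS_NAMES[j]}",
                    role="corr",
                )
            )
        for b in range(len(BAND_EDGES)):
            triplet(sig, FeaturePrimitive.BANDS_ENERGY, band=b)

    return entries


def build_manifests() -> tuple[FeatureManifest, FeatureManifest]:
    """Construct the AXIS_DEP (254) and ROT_INV (90) reference manifests."""
    axis_entries = _axis_entries()
    names = [e.name for e in axis_entries]
    reduced: list[ReducedEntry] = []
    seen_groups: set[str] = set()
    for idx, e in enumerate(axis_entries):
        if e.role == "corr":
            continue
        if e.role == "scalar":
            src = idx
            name = e.name
            if e.primitive is FeaturePrimitive.SMA and e.signal in TRIAXIAL_TIME_SIGNALS:
                # the L1 magnitude area is orientation sensitive; its
                # rotation-invariant analogue is the mean L2 magnitude,
                # already present as the magnitude-signal MEAN feature
                src = names.index(f"mag_{e.signal}_mean")
                name = f"{e.signal}_sma_l2"
            reduced.append(ReducedEntry(name=name, source_indices=(src,), kind="pass"))
            continue
        if e.group in seen_groups:
            continue
        seen_groups.add(e.group)
        members = tuple(
            i for i, m in enumerate(axis_entries) if m.role == "triplet" and m.group == e.group
        )
        assert len(members) == 3
        kind = "sqrt_sum" if e.primitive in _QUADRATIC else "norm"
        reduced.append(ReducedEntry(name=f"{e.group}_mag3", source_indices=members, kind=kind))
    axis = FeatureManifest("AXIS_DEP", axis_entries)
    rotinv = FeatureManifest("ROT_INV", reduced)
    if len(axis) != AXIS_MANIFEST_LENGTH or len(rotinv) != ROTINV_MANIFEST_LENGTH:
        raise AssertionError(
            f"reference manifests must emit {AXIS_MANIFEST_LENGTH}/{ROTINV_MANIFEST_LENGTH}"
            f" features, got {len(axis)}/{len(rotinv)}"
        )
    return axis, rotinv


AXIS_MANIFEST, ROTINV_MANIFEST = build_manifests()


# ---------------------------------------------------------------------------
# primitive evaluation


def spectrum64(windows: np.ndarray) -> np.ndarray:
    """One-sided 64-bin magnitude spectrum of mean-removed windows.

    ``windows`` is (n_windows, window_len); output is (n_windows, 64) from a
    zero-padded length-128 FFT (rectangular window).
    """
    x = np.atleast_2d(np.asarray(windows, dtype=float))
    x = x - x.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(x, n=N_FFT, axis=1))[:, :N_SPECTRUM_BINS]
    return spec


def _yule_walker_batch(windows: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Yule-Walker AR coefficients per window, shape (n_windows, order)."""
    x = windows - windows.mean(axis=1, keepdims=True)
    n = x.shape[1]
    r = np.stack(
        [np.einsum("ij,ij->i", x[:, : n - k], x[:, k:]) / n for k in range(order + 1)],
        axis=1,
    )
    degenerate = r[:, 0] <= 1e-30
    r = r.copy()
    r[degenerate, 0] = 1.0
    idx = np.abs(np.subtract.outer(np.arange(order), np.arange(order)))
    R = r[:, idx]  # (n_windows, order, order) Toeplitz autocovariance
    rhs = r[:, 1 : order + 1]
    # tiny ridge keeps near-degenerate windows solvable
    R = R + 1e-12 * np.eye(order)
    coef = np.linalg.solve(R, rhs[..., None])[..., 0]
    coef[degenerate] = 0.0
    return coef


def _correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a0 = a - a.mean(axis=1, keepdims=True)
    b0 = b - b.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", a0, b0)
    den = np.sqrt(np.einsum("ij,ij->i", a0, a0) * np.einsum("ij,ij->i", b0, b0))
    out = np.zeros(len(a))
    ok = den > 0
    if not ok.all():
        warnings.warn("zero-variance input to CORRELATION; defined as 0", stacklevel=3)
    out[ok] = num[ok] / den[ok]
    return out


def _entropy_of_spectrum(spec: np.ndarray) -> np.ndarray:
    total = spec.sum(axis=1, keepdims=True)
    safe = np.where(total > 0, total, 1.0)
    p = spec / safe
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    h[total[:, 0] <= 0] = 0.0
    return h


class _WindowContext:
    """Caches windowed signals, spectra and batch primitives per extraction."""

    def __init__(self, signals: dict[str, np.ndarray], starts: np.ndarray,
                 window_len: int, fs: float):
        self._signals = signals
        self._starts = np.asarray(starts, dtype=int)
        self._wl = int(window_len)
        self._fs = float(fs)
        self._cache: dict = {}

    def _window(self, arr: np.ndarray) -> np.ndarray:
        return np.stack([arr[s : s + self._wl] for s in self._starts])

    def time_axis(self, signal: str, axis: Optional[int]) -> np.ndarray:
        key = ("t", signal, axis)
        if key not in self._cache:
            if signal not in self._signals:
                raise ManifestError(f"manifest references missing signal {signal!r}")
            arr = self._signals[signal]
            arr = arr if axis is None else arr[:, axis]
            self._cache[key] = self._window(arr)
        return self._cache[key]

    def values(self, signal: str, axis: Optional[int]) -> np.ndarray:
        """The array a stat primitive operates on: window samples for time
        signals, 64 spectrum magnitudes for frequency signals."""
        if signal in FREQ_SOURCE:
            return self.spectrum(FREQ_SOURCE[signal], axis)
        return self.time_axis(signal, axis)

    def spectrum(self, time_signal: str, axis: Optional[int]) -> np.ndarray:
        key = ("f", time_signal, axis)
        if key not in self._cache:
            self._cache[key] = spectrum64(self.time_axis(time_signal, axis))
        return self._cache[key]

    def ar_coefs(self, signal: str, axis: int) -> np.ndarray:
        key = ("ar", signal, axis)
        if key not in self._cache:
            self._cache[key] = _yule_walker_batch(self.time_axis(signal, axis))
        return self._cache[key]

    @property
    def bin_freqs(self) -> np.ndarray:
        return np.arange(N_SPECTRUM_BINS) * self._fs / N_FFT

    def evaluate(self, e: FeatureEntry) -> np.ndarray:
        p = e.primitive
        if p is FeaturePrimitive.AR_COEF:
            return self.ar_coefs(e.signal, e.axis)[:, e.order]
        if p is FeaturePrimitive.CORRELATION:
            i, j = e.pair
            return _correlation(self.values(e.signal, i), self.values(e.signal, j))
        if p is FeaturePrimitive.SMA:
            if e.signal in MAGNITUDE_SIGNALS:
                return np.abs(self.values(e.signal, None)).mean(axis=1)
            return sum(
                np.abs(self.values(e.signal, ax)) for ax in range(3)
            ).mean(axis=1)
        if p is FeaturePrimitive.ENTROPY:
            if e.signal in FREQ_SOURCE:
                spec = self.values(e.signal, e.axis)
            elif e.signal in MAGNITUDE_SIGNALS:
                spec = self.spectrum(e.signal, None)
            else:
                spec = self.spectrum(e.signal, e.axis)
            return _entropy_of_spectrum(spec)
        v = self.values(e.signal, e.axis)
        if p is FeaturePrimitive.MEAN:
            return v.mean(axis=1)
        if p is FeaturePrimitive.STD:
            return v.std(axis=1)
        if p is FeaturePrimitive.MAD:
            return np.median(np.abs(v - np.median(v, axis=1, keepdims=True)), axis=1)
        if p is FeaturePrimitive.MAX:
            return v.max(axis=1)
        if p is FeaturePrimitive.MIN:
            return v.min(axis=1)
        if p is FeaturePrimitive.ENERGY:
            return np.einsum("ij,ij->i", v, v) / v.shape[1]
        if p is FeaturePrimitive.IQR:
            q75, q25 = np.percentile(v, [75, 25], axis=1)
            return q75 - q25
        if p is FeaturePrimitive.MAX_FREQ_IND:
            return v.argmax(axis=1).astype(float)
        if p is FeaturePrimitive.MEAN_FREQ:
            total = v.sum(axis=1)
            safe = np.where(total > 0, total, 1.0)
            mf = (v * self.bin_freqs).sum(axis=1) / safe
            mf[total <= 0] = 0.0
            return mf
        if p is FeaturePrimitive.SKEWNESS_F:
            # constant spectrum (e.g. an all-zero window) has no shape: 0
            return np.nan_to_num(sp_stats.skew(v, axis=1), nan=0.0)
        if p is FeaturePrimitive.KURTOSIS_F:
            return np.nan_to_num(sp_stats.kurtosis(v, axis=1), nan=0.0)
        if p is FeaturePrimitive.BANDS_ENERGY:
            lo, hi = BAND_EDGES[e.band]
            band = v[:, lo:hi]
            return np.einsum("ij,ij->i", band, band) / band.shape[1]
        raise ManifestError(f"unhandled primitive {p}")  # pragma: no cover


def primitive_value(primitive: FeaturePrimitive, *signals: np.ndarray,
                    fs: float = 25.0, **params):
    """Evaluate a single primitive on one window (convenience wrapper).

    Stat primitives take one signal; CORRELATION takes two; AR_COEF returns
    the full coefficient vector of the requested ``order``.
    """
    x = np.atleast_2d(np.asarray(signals[0], dtype=float))
    if primitive is FeaturePrimitive.CORRELATION:
        y = np.atleast_2d(np.asarray(signals[1], dtype=float))
        return float(_correlation(x, y)[0])
    if primitive is FeaturePrimitive.AR_COEF:
        order = params.get("order", AR_ORDER)
        return _yule_walker_batch(x, order=order)[0]
    if primitive is FeaturePrimitive.SMA:
        if len(signals) == 3:
            tri = np.stack([np.asarray(s, dtype=float) for s in signals], axis=-1)
            return float(np.abs(tri).sum(axis=-1).mean())
        return float(np.abs(x).mean())
    freq_prims = {
        FeaturePrimitive.MAX_FREQ_IND,
        FeaturePrimitive.MEAN_FREQ,
        FeaturePrimitive.SKEWNESS_F,
        FeaturePrimitive.KURTOSIS_F,
        FeaturePrimitive.BANDS_ENERGY,
    }
    signal = "f_body_acc" if primitive in freq_prims else "body_acc"
    ctx_signals = {"body_acc": np.column_stack([x[0]] * 3)}
    ctx = _WindowContext(ctx_signals, np.array([0]), x.shape[1], fs)
    entry = FeatureEntry(signal=signal, primitive=primitive, axis=0,
                         band=params.get("band"), name="tmp")
    return float(ctx.evaluate(entry)[0])


def extract_matrix(
    bundle: SignalBundle,
    starts: np.ndarray,
    window_len: int,
    fs: float,
    manifest: FeatureManifest = AXIS_MANIFEST,
) -> np.ndarray:
    """Feature matrix (n_windows x n_features) for windows of a bundle."""
    if not isinstance(manifest.entries[0], FeatureEntry):
        axis = extract_matrix(bundle, starts, window_len, fs, AXIS_MANIFEST)
        return rotation_invariant_reduce(axis, ROTINV_MANIFEST)
    ctx = _WindowContext(bundle.signals(), starts, window_len, fs)
    cols = [ctx.evaluate(e) for e in manifest.entries]
    return np.column_stack(cols)


def extract_features(
    bundle: SignalBundle,
    manifest: FeatureManifest = AXIS_MANIFEST,
    fs: float = 25.0,
) -> np.ndarray:
    """Feature vector for a single fully-windowed bundle."""
    n = len(bundle.mag_body_acc)
    return extract_matrix(bundle, np.array([0]), n, fs, manifest)[0]


def rotation_invariant_reduce(
    axis_features: np.ndarray, manifest: FeatureManifest = ROTINV_MANIFEST
) -> np.ndarray:
    """Collapse an AXIS_DEP feature matrix/vector to the ROT_INV layout."""
    X = np.atleast_2d(np.asarray(axis_features, dtype=float))
    if X.shape[1] != AXIS_MANIFEST_LENGTH:
        raise ManifestError(
            f"expected axis-dependent layout of {AXIS_MANIFEST_LENGTH} features,"
            f" got {X.shape[1]}"
        )
    out = np.empty((X.shape[0], len(manifest)))
    for j, e in enumerate(manifest.entries):
        src = X[:, list(e.source_indices)]
        if e.kind == "pass":
            out[:, j] = src[:, 0]
        elif e.kind == "norm":
            out[:, j] = np.sqrt((src**2).sum(axis=1))
        elif e.kind == "sqrt_sum":
            out[:, j] = np.sqrt(np.clip(src.sum(axis=1), 0.0, None))
        else:  # pragma: no cover
            raise ManifestError(f"unknown reduction kind {e.kind!r}")
    if axis_features.ndim == 1:
        return out[0]
    return out


# ---------------------------------------------------------------------------
# z-score scaling


@dataclass
class ScalerParams:
    mean: np.ndarray
    std: np.ndarray     # zero-variance columns stored as std 0, applied as 1

    def __len__(self) -> int:
        return len(self.mean)


def fit_scaler(X: np.ndarray) -> ScalerParams:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("fit_scaler needs a 2-D matrix with >= 2 rows")
    return ScalerParams(mean=X.mean(axis=0), std=X.std(axis=0))


def apply_scaler(X: np.ndarray, params: ScalerParams) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(params):
        raise ValueError(
            f"row length {X.shape[1]} does not match scaler length {len(params)}"
        )
    divisor = np.where(params.std > 0, params.std, 1.0)
    return (X - params.mean) / divisor
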