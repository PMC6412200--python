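"""Orientation checking and model routing.

Every incoming recording is checked against the reference measurement
space defined by the (consistently oriented) training recordings; the check
decides whether the axis-dependent classifier applies or the recording must
fall back to the rotation-invariant surrogate.

Two rules fire in order:

1. *Vertical-axis check* — gravity makes the vertical axis (``acc_x``,
   worn with -X up) the most prominent one; the bulk of the test values
   (central 80%, i.e. the [p10, p90] interval) must fall inside the pooled
   training interval, expanded by a small margin.
2. *Distribution check* — for baseline-shifted signals that fail rule 1,
   the recording (after baseline alignment) is compared with each training
   recording via a 3-D Kolmogorov-Smirnov distance on 16^3 histograms of
   the raw tri-axial values; if the minimum distance stays below the
   threshold theta (the maximum within-training pairwise distance), the
   orientation is still considered correct.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .core_io import Recording
from .harmonize import BaselineVector, align_baseline, estimate_baseline

logger = logging.getLogger(__name__)

N_BINS = 16
TAIL_CLIP = 0.01          # pooled-range clipping per axis when fixing bin edges
VERTICAL_AXIS = "acc_x"
RULE1_MARGIN = 0.10       # fraction of the reference interval width
MAX_HISTOGRAM_S = 3600.0  # use up to the first hour of signal


class ModelChoice(str, Enum):
    AXIS_DEPENDENT = "AXIS_DEPENDENT"
    ROTATION_INVARIANT = "ROTATION_INVARIANT"


class GridError(ValueError):
    """Raised when histograms with mismatched bin edges are compared."""


@dataclass
class Histogram3D:
    """Normalized 3-D histogram of tri-axial accelerometer values."""

    bin_edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    counts: np.ndarray          # (B, B, B)
    normalized: bool = True

    @classmethod
    def from_acc(
        cls, acc: np.ndarray, bin_edges: Sequence[np.ndarray]
    ) -> "Histogram3D":
        """Histogram accelerometer samples, clamping values into the grid so
        no probability mass is lost for out-of-range recordings."""
        acc = np.asarray(acc, dtype=float)
        clamped = np.column_stack(
            [
                np.clip(acc[:, i], bin_edges[i][0], bin_edges[i][-1])
                for i in range(3)
            ]
        )
        counts, _ = np.histogramdd(clamped, bins=list(bin_edges))
        total = counts.sum()
        if total > 0:
            counts = counts / total
        return cls(bin_edges=tuple(np.asarray(e) for e in bin_edges), counts=counts)


def ks3d(a: Histogram3D, b: Histogram3D) -> float:
    """3-D Kolmogorov-Smirnov distance between two binned distributions.

    Fasano-Franceschini-style statistic: cumulate both histograms along each
    of the 8 octant direction combinations and take the maximum absolute
    difference over all bins and directions.  Symmetric, in [0, 1].
    """
    for ea, eb in zip(a.bin_edges, b.bin_edges):
        if ea.shape != eb.shape or not np.allclose(ea, eb):
            raise GridError("histograms live on different bin grids")
    if not (a.normalized and b.normalized):
        raise GridError("ks3d requires normalized histograms")
    diff = a.counts - b.counts
    best = 0.0
    for flips in itertools.product((False, True), repeat=3):
        d = diff
        for ax, flip in enumerate(flips):
            if flip:
                d = np.flip(d, axis=ax)
        c = d
        for ax in range(3):
            c = np.cumsum(c, axis=ax)
        best = max(best, float(np.abs(c).max()))
    return min(best, 1.0)


@dataclass
class ReferenceSpace:
    """Training-set signatures for orientation checking."""

    vertical_axis: str
    vertical_interval: tuple[float, float]
    bin_edges: tuple[np.ndarray, np.ndarray, np.ndarray]
    reference_histograms: list[Histogram3D]
    theta: float
    reference_baseline: BaselineVector

    def __post_init__(self) -> None:
        low, high = self.vertical_interval
        if not low < high:
            raise ValueError("vertical interval must have low < high")


def _first_hour(rec: Recording) -> np.ndarray:
    n = min(rec.n_samples, int(MAX_HISTOGRAM_S * rec.sampling_rate_hz))
    return rec.acc()[:n]


def fit_reference_space(
    train_recs: Sequence[Recording], bins: int = N_BINS
) -> ReferenceSpace:
    """Learn the reference measurement space from >= 2 training recordings."""
    if len(train_recs) < 2:
        raise ValueError("need >= 2 training recordings to calibrate theta")
    vert = [r.channels[VERTICAL_AXIS] for r in train_recs]
    p10 = min(float(np.percentile(v, 10)) for v in vert)
    p90 = max(float(np.percentile(v, 90)) for v in vert)

    # the reference histograms live in the baseline-corrected space, like
    # every test histogram rule 2 will compare against
    baselines = np.stack([estimate_baseline(r).values for r in train_recs])
    ref_baseline = BaselineVector(baselines.mean(axis=0))
    aligned = [align_baseline(r, ref_baseline) for r in train_recs]
    accs = [_first_hour(r) for r in aligned]

    pooled = np.concatenate(accs, axis=0)
    edges = tuple(
        np.linspace(
            np.quantile(pooled[:, i], TAIL_CLIP),
            np.quantile(pooled[:, i], 1 - TAIL_CLIP),
            bins + 1,
        )
        for i in range(3)
    )
    hists = [Histogram3D.from_acc(a, edges) for a in accs]
    theta = max(
        (ks3d(h1, h2) for h1, h2 in itertools.combinations(hists, 2)),
        default=0.0,
    )
    return ReferenceSpace(
        vertical_axis=VERTICAL_AXIS,
        vertical_interval=(p10, p90),
        bin_edges=edges,
        reference_histograms=hists,
        theta=theta,
        reference_baseline=ref_baseline,
    )


def vertical_axis_check(
    rec: Recording, space: ReferenceSpace, margin: float = RULE1_MARGIN
) -> bool:
    """Rule 1: test central-80% interval inside the expanded reference one."""
    v = rec.channels[space.vertical_axis]
    t10, t90 = np.percentile(v, [10, 90])
    low, high = space.vertical_interval
    m = margin * (high - low)
    return bool(low - m <= t10 and t90 <= high + m)


def min_reference_distance(rec: Recording, space: ReferenceSpace) -> float:
    """Rule-2 statistic: minimum ks3d distance to any training histogram."""
    hist = Histogram3D.from_acc(_first_hour(rec), space.bin_edges)
    return min(ks3d(hist, ref) for ref in space.reference_histograms)


def select_model(
    rec: Recording,
    space: ReferenceSpace,
    margin: float = RULE1_MARGIN,
) -> ModelChoice:
    """Route a recording to the axis-dependent or rotation-invariant model.

    Rule 1 sees the recording as given (a shifted baseline must be able to
    fail it); rule 2 compares 3-D histograms after aligning the recording to
    the reference baseline, so a pure shift is forgiven but a rotation is
    not.  The decision and the rule that fired are logged.
    """
    if vertical_axis_check(rec, space, margin):
        logger.info(
            "subject=%s rule=1 model=%s", rec.subject_id, ModelChoice.AXIS_DEPENDENT.value
        )
        return ModelChoice.AXIS_DEPENDENT
    aligned = align_baseline(rec, space.reference_baseline)
    min_dist = min_reference_distance(aligned, space)
    choice = (
        ModelChoice.AXIS_DEPENDENT
        if min_dist < space.theta
        else ModelChoice.ROTATION_INVARIANT
    )
    logger.info(
        "subject=%s rule=2 model=%s min_dist=%.4f theta=%.4f",
        rec.subject_id, choice.value, min_dist, space.theta,
    )
    return choice
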