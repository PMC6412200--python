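"""Temporal coherency of predicted activity sequences.

Predictions are made per window independently, so isolated misclassified
windows show up as impulse noise in the activity sequence.  Assuming every
activity lasts at least a minimum duration (4 s by default — appropriate
for the unhurried transitions of older adults), a centered moving majority
vote over the prediction lattice removes such impulses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import ActivityLabel
from .orientation import ModelChoice

MIN_DURATION_S = 4.0
HOP_S = 34 / 25.0  # prediction lattice spacing: 1.36 s


def smoothing_window(min_duration_s: float = MIN_DURATION_S, hop_s: float = HOP_S) -> int:
    """Filter support: nearest odd integer to min_duration / hop (>= 1)."""
    w = int(round(min_duration_s / hop_s))
    if w % 2 == 0:
        # round to the *nearest* odd integer
        w += 1 if (min_duration_s / hop_s) >= w else -1
    return max(w, 1)


def majority_smooth(
    labels: Sequence, min_duration_s: float = MIN_DURATION_S, hop_s: float = HOP_S
) -> list:
    """Centered moving majority vote over a label sequence.

    Edge windows are truncated; a tie keeps the incumbent (current) label
    to avoid oscillation.  Output length equals input length and the output
    alphabet is a subset of the input alphabet.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("majority_smooth needs a non-empty sequence")
    w = smoothing_window(min_duration_s, hop_s)
    half = w // 2
    out = []
    for i, current in enumerate(labels):
        neigh = labels[max(0, i - half) : i + half + 1]
        counts: dict = {}
        for lab in neigh:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        out.append(current if current in winners else
                   max(counts, key=lambda k: (counts[k], k == current)))
    return out


@dataclass
class PredictionSeries:
    """Per-window labels before/after smoothing, with their start times."""

    window_start_s: np.ndarray
    raw_labels: list[ActivityLabel]
    model_used: ModelChoice
    hop_s: float = HOP_S
    smoothed_labels: Optional[list[ActivityLabel]] = None

    def __post_init__(self) -> None:
        if len(self.window_start_s) != len(self.raw_labels):
            raise ValueError("start times and labels must align")

    def smooth(self, min_duration_s: float = MIN_DURATION_S) -> "PredictionSeries":
        self.smoothed_labels = majority_smooth(
            self.raw_labels, min_duration_s, self.hop_s
        )
        return self

    def to_frame(self) -> pd.DataFrame:
        smoothed = self.smoothed_labels or [None] * len(self.raw_labels)
        return pd.DataFrame(
            {
                "window_start_s": self.window_start_s,
                "label_raw": [l.value for l in self.raw_labels],
                "label_smoothed": [l.value if l else "" for l in smoothed],
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
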