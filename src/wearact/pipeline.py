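"""End-to-end orchestration and evaluation.

`run_train` / `run_predict` / `run_evaluate` tie the stages together over
directories of CSV recordings and annotation tracks; `evaluate_cohort`
does the same in memory for a synthetic cohort.  Accuracy is computed per
window against majority-rule ground-truth window labels, then aggregated
per subject; the report carries the 5x5 row-normalized confusion matrix
and the model-routing table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .classify import ModelBundle, predict_windows, train_bundle
from .core_io import (
    ActivityLabel,
    AnnotationTrack,
    Recording,
    build_labels,
    read_annotations,
    read_recording,
    segment_windows,
    CHANNELS_3,
    CHANNELS_9,
)
from .orientation import ModelChoice
from .synthetic import Cohort, CohortSubject
from .temporal import PredictionSeries

logger = logging.getLogger(__name__)

LABEL_ORDER = [l.value for l in ActivityLabel]


@dataclass
class EvalReport:
    overall_accuracy_pct: float
    confusion_pct: np.ndarray                  # 5x5, rows sum to 100
    per_subject_accuracy_pct: dict[str, float]
    routing: dict[str, str]                    # subject -> model used

    def to_dict(self) -> dict:
        return {
            "overall_accuracy_pct": self.overall_accuracy_pct,
            "labels": LABEL_ORDER,
            "confusion_pct": self.confusion_pct.tolist(),
            "per_subject_accuracy_pct": self.per_subject_accuracy_pct,
            "routing": self.routing,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def __str__(self) -> str:
        lines = [f"overall accuracy: {self.overall_accuracy_pct:.2f}%", "confusion (%):"]
        header = "".join(f"{l[:9]:>11}" for l in LABEL_ORDER)
        lines.append(" " * 11 + header)
        for lab, row in zip(LABEL_ORDER, self.confusion_pct):
            lines.append(f"{lab[:9]:>11}" + "".join(f"{v:11.2f}" for v in row))
        for sid, acc in self.per_subject_accuracy_pct.items():
            lines.append(f"subject {sid}: {acc:.2f}% ({self.routing.get(sid, '-')})")
        return "\n".join(lines)


def truth_window_labels(rec: Recording, track: AnnotationTrack) -> list:
    """Majority-rule ground-truth labels on the prediction lattice."""
    ws = segment_windows(rec, build_labels(track))
    return ws.labels


def confusion_matrix_pct(y_true: Sequence, y_pred: Sequence) -> np.ndarray:
    cm = np.zeros((len(LABEL_ORDER), len(LABEL_ORDER)))
    index = {lab: i for i, lab in enumerate(LABEL_ORDER)}
    for t, p in zip(y_true, y_pred):
        cm[index[str(t)], index[str(p)]] += 1
    rows = cm.sum(axis=1, keepdims=True)
    return np.divide(cm, rows, out=np.zeros_like(cm), where=rows > 0) * 100.0


def evaluate_predictions(
    per_subject: dict[str, tuple[Sequence, Sequence]],
    routing: Optional[dict[str, str]] = None,
) -> EvalReport:
    """Window-level evaluation from {subject: (y_true, y_pred)}."""
    all_true, all_pred, per_subj = [], [], {}
    for sid, (y_true, y_pred) in per_subject.items():
        y_true = [str(t) for t in y_true]
        y_pred = [str(p) for p in y_pred]
        if len(y_true) != len(y_pred):
            raise ValueError(f"label length mismatch for subject {sid}")
        per_subj[sid] = 100.0 * float(np.mean(np.array(y_true) == np.array(y_pred)))
        all_true += y_true
        all_pred += y_pred
    overall = 100.0 * float(np.mean(np.array(all_true) == np.array(all_pred)))
    return EvalReport(
        overall_accuracy_pct=overall,
        confusion_pct=confusion_matrix_pct(all_true, all_pred),
        per_subject_accuracy_pct=per_subj,
        routing=routing or {},
    )


def predict_subject(
    subj: CohortSubject, bundle: ModelBundle, *, smooth: bool = True,
    force_model: Optional[ModelChoice] = None,
) -> tuple[list, list, PredictionSeries]:
    """(y_true, y_pred, series) for one cohort subject."""
    series = predict_windows(subj.recording, bundle, force_model=force_model)
    if smooth:
        series.smooth()
    truth = truth_window_labels(subj.recording, subj.track)
    pred = series.smoothed_labels if smooth else series.raw_labels
    keep = [i for i, t in enumerate(truth) if t is not None]
    return (
        [truth[i].value for i in keep],
        [pred[i].value for i in keep],
        series,
    )


def evaluate_cohort(
    subjects: Sequence[CohortSubject], bundle: ModelBundle, *, smooth: bool = True
) -> EvalReport:
    per_subject, routing = {}, {}
    for subj in subjects:
        y_true, y_pred, series = predict_subject(subj, bundle, smooth=smooth)
        sid = subj.recording.subject_id
        per_subject[sid] = (y_true, y_pred)
        routing[sid] = series.model_used.value
    return evaluate_predictions(per_subject, routing)


# ---------------------------------------------------------------------------
# directory-level entry points (the CLI is a thin wrapper over these)


def _load_dir(recordings_dir, annotations_dir) -> tuple[list[Recording], list[AnnotationTrack]]:
    rec_dir, ann_dir = Path(recordings_dir), Path(annotations_dir)
    if not rec_dir.is_dir():
        raise FileNotFoundError(f"recordings directory {rec_dir} does not exist")
    recs, tracks = [], []
    for path in sorted(rec_dir.glob("*.csv")):
        ann = ann_dir / path.name.replace("recording", "annotations")
        if not ann.exists():
            ann = ann_dir / path.name
        if not ann.exists():
            raise FileNotFoundError(f"no annotation file for {path.name}")
        import pandas as pd

        cols = pd.read_csv(path, nrows=0).columns
        schema = CHANNELS_9 if set(CHANNELS_9).issubset(cols) else CHANNELS_3
        recs.append(read_recording(path, schema, subject_id=path.stem))
        tracks.append(read_annotations(ann))
    if not recs:
        raise FileNotFoundError(f"no recording CSVs in {rec_dir}")
    return recs, tracks


def run_train(recordings_dir, annotations_dir, out_path, *, seed: int = 0) -> ModelBundle:
    from .classify import SvmConfig

    recs, tracks = _load_dir(recordings_dir, annotations_dir)
    bundle = train_bundle(recs, tracks, config=SvmConfig(seed=seed))
    bundle.save(out_path)
    logger.info("bundle written to %s", out_path)
    return bundle


def run_predict(
    recording_path, bundle_path, out_path, *, smooth: bool = True
) -> PredictionSeries:
    import pandas as pd

    bundle = ModelBundle.load(bundle_path)
    cols = pd.read_csv(recording_path, nrows=0).columns
    schema = CHANNELS_9 if set(CHANNELS_9).issubset(cols) else CHANNELS_3
    rec = read_recording(recording_path, schema, subject_id=Path(recording_path).stem)
    series = predict_windows(rec, bundle)
    if smooth:
        series.smooth()
    series.write_csv(out_path)
    return series


def run_evaluate(predictions_csv, recording_path, annotations_path) -> EvalReport:
    import pandas as pd

    df = pd.read_csv(predictions_csv)
    col = "label_smoothed" if df["label_smoothed"].astype(bool).all() else "label_raw"
    pred = df[col].tolist()
    cols = pd.read_csv(recording_path, nrows=0).columns
    schema = CHANNELS_9 if set(CHANNELS_9).issubset(cols) else CHANNELS_3
    rec = read_recording(recording_path, schema, subject_id=Path(recording_path).stem)
    truth = truth_window_labels(rec, read_annotations(annotations_path))
    keep = [i for i, t in enumerate(truth) if t is not None]
    sid = Path(recording_path).stem
    return evaluate_predictions(
        {sid: ([truth[i].value for i in keep], [pred[i] for i in keep])}
    )
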