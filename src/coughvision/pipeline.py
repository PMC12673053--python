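"""End-to-end plumbing: cohort on disk -> segments -> features -> model.

Helpers used by the command-line interface, the cross-validation runner
and the end-to-end checks. Images are produced and consumed in chunks so
a full cohort never has to hold every 224x224 RGB array in memory at
once; only the backend's (much smaller) feature matrix is retained.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .audio import CoughAnnotation, Recording, load_annotation, load_recording
from .evaluation import (
    ConfusionMatrix,
    MetricsReport,
    grouped_metrics,
    metrics,
    metrics_table,
)
from .segmentation import SlidingWindowSegmenter
from .spectrogram import SpectrogramConfig, SpectrogramImager
from .split import SplitAssignment, assign_splits, cough_rate
from .training import ClassifierBackend, PixelLogisticBackend, TrainConfig, train


def load_cohort(
    cohort_dir: str | Path,
) -> tuple[dict[str, Recording], dict[str, CoughAnnotation], pd.DataFrame]:
    """Load a generated cohort (audio/, annotations/, metadata.csv)."""
    cohort_dir = Path(cohort_dir)
    meta = pd.read_csv(cohort_dir / "metadata.csv")
    recordings: dict[str, Recording] = {}
    annotations: dict[str, CoughAnnotation] = {}
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        rec = load_recording(cohort_dir / "audio" / f"{sid}.wav", subject_id=sid)
        recordings[sid] = rec
        annotations[sid] = load_annotation(
            cohort_dir / "annotations" / f"{sid}.csv", rec
        )
    return recordings, annotations, meta


def segment_cohort(
    recordings: dict[str, Recording],
    annotations: dict[str, CoughAnnotation],
    segment_ms: int,
    reference_anchor: str = "onset",
) -> pd.DataFrame:
    """Labelled segment table for a whole cohort.

    Columns: subject_id, segment_index, start (samples), length, label
    (0/1), source_event (annotation event index, -1 for non-cough).
    """
    segmenter = SlidingWindowSegmenter(segment_ms, reference_anchor)
    rows = []
    for sid in sorted(recordings):
        for seg in segmenter.transform(recordings[sid], annotations[sid]):
            rows.append(
                {
                    "subject_id": sid,
                    "segment_index": seg.segment_index,
                    "start": seg.start,
                    "length": seg.length,
                    "label": 1 if seg.label == "cough" else 0,
                    "source_event": seg.source_event if seg.source_event is not None else -1,
                }
            )
    return pd.DataFrame(rows)


def extract_features(
    recordings: dict[str, Recording],
    segments: pd.DataFrame,
    config_id: str,
    backend: ClassifierBackend,
    chunk_size: int = 512,
) -> np.ndarray:
    """Backend feature matrix for every segment row, streamed in chunks."""
    imager = SpectrogramImager(config_id)
    floats = {sid: rec.as_float() for sid, rec in recordings.items()}
    feats: list[np.ndarray] = []
    for lo in range(0, len(segments), chunk_size):
        block = segments.iloc[lo : lo + chunk_size]
        audio = np.stack(
            [
                floats[r.subject_id][r.start : r.start + r.length]
                for r in block.itertuples(index=False)
            ]
        )
        feats.append(backend.prepare(imager.transform(audio)))
    return np.concatenate(feats, axis=0)


def cohort_rates(meta: pd.DataFrame, annotations: dict[str, CoughAnnotation]) -> pd.DataFrame:
    """Subject table (subject_id, category, sex, cough_rate) for splitting."""
    rows = []
    for row in meta.itertuples(index=False):
        sid = str(row.subject_id)
        rows.append(
            {
                "subject_id": sid,
                "category": row.category,
                "sex": row.sex,
                "cough_rate": cough_rate(len(annotations[sid]), row.duration_s),
            }
        )
    return pd.DataFrame(rows)


def run_experiment(
    cohort_dir: str | Path,
    config_id: str = "750_128_32",
    seed: int = 0,
    train_config: TrainConfig | None = None,
    backend: ClassifierBackend | None = None,
    assignment: SplitAssignment | None = None,
) -> dict:
    """Full chain on a cohort: segment, image, split, train, evaluate.

    Returns a dict with the split assignment, per-epoch history, the
    overall test report, per-subject and per-category reports, and the raw
    prediction table (subject_id, category, y_true, y_pred).
    """
    config = SpectrogramConfig.from_id(config_id)
    recordings, annotations, meta = load_cohort(cohort_dir)
    segments = segment_cohort(recordings, annotations, config.segment_ms)
    subjects = cohort_rates(meta, annotations)
    if assignment is None:
        assignment = assign_splits(subjects, seed=seed)

    backend = backend or PixelLogisticBackend()
    features = extract_features(recordings, segments, config_id, backend)
    y = segments["label"].to_numpy()
    subj = segments["subject_id"].to_numpy()
    split_of = segments["subject_id"].map(assignment.mapping).to_numpy()

    tc = train_config or TrainConfig(seed=seed)
    tr, va, te = (split_of == s for s in ("train", "validation", "test"))
    fitted, history = train(
        backend,
        features[tr], y[tr], features[va], y[va], tc,
        train_subjects=subj[tr], val_subjects=subj[va],
        prepared=True,
    )

    scores = fitted.predict_scores(features[te])
    preds = (scores >= 0.5).astype(int)
    cat_of = dict(zip(meta["subject_id"].astype(str), meta["category"]))
    pred_df = pd.DataFrame(
        {
            "subject_id": subj[te],
            "category": [cat_of[s] for s in subj[te]],
            "y_true": y[te],
            "y_pred": preds,
        }
    )
    overall = metrics(ConfusionMatrix.from_predictions(y[te], preds))
    return {
        "assignment": assignment,
        "history": history,
        "overall": overall,
        "per_subject": grouped_metrics(pred_df, "subject"),
        "per_category": grouped_metrics(pred_df, "category"),
        "predictions": pred_df,
    }


def make_fold_train_fn(
    train_config: TrainConfig,
    backend_factory=None,
    val_fraction: float = 0.2,
):
    """A ``train_fn`` for :func:`coughvision.evaluation.kfold_cv`.

    Each fold holds out a seeded fraction of its training samples for the
    early-stopping monitor, fits a fresh backend, and scores the fold's
    evaluation samples.
    """
    backend_factory = backend_factory or (lambda: PixelLogisticBackend())

    def train_fn(F_tr: np.ndarray, y_tr: np.ndarray, F_te: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(train_config.seed)
        order = rng.permutation(len(y_tr))
        n_val = max(1, int(round(val_fraction * len(y_tr))))
        va_idx, tr_idx = order[:n_val], order[n_val:]
        backend = backend_factory()
        fitted, _ = train(
            backend,
            F_tr[tr_idx], y_tr[tr_idx], F_tr[va_idx], y_tr[va_idx],
            train_config, prepared=True,
        )
        return fitted.predict_scores(F_te)

    return train_fn
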