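"""Confusion-matrix metrics at overall, per-subject and per-category level.

Four metrics are derived from segment-level confusion counts:

- sensitivity (recall) = TP / (TP + FN)
- specificity           = TN / (TN + FP)
- precision             = TP / (TP + FP)
- F1                    = harmonic mean of precision and sensitivity

Metrics are kept at full precision internally and rounded half-up to two
decimal places (as percentages) only at presentation. A ratio with a zero
denominator is *undefined* and reported as absent with a reason — never
silently coerced to 0 or 100. This matters for zero-cough subjects
(healthy volunteers can produce none), which are excluded from
sensitivity/F1 summaries with a logged reason.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold, KFold

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Segment-level confusion counts for the binary cough task."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fp + other.fp,
            self.tn + other.tn, self.fn + other.fn,
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same shape")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def _round2(x: float) -> float:
    """Half-up rounding to 2 decimals (presentation only)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MetricsReport:
    """The four metrics as percentages; undefined ratios flagged by name."""

    cm: ConfusionMatrix
    group: str = "overall"
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f1: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def rounded(self) -> dict[str, float | None]:
        """Metrics rounded half-up to two decimals for presentation."""
        return {
            k: (_round2(v) if v is not None else None)
            for k, v in {
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
                "f1": self.f1,
            }.items()
        }


def metrics(cm: ConfusionMatrix, group: str = "overall") -> MetricsReport:
    """Compute sensitivity, specificity, precision and F1 (percentages).

    Any metric whose denominator is zero is left ``None`` with a reason in
    ``report.undefined`` (e.g. sensitivity for a subject with no cough
    events). F1 of a classifier that finds nothing (precision and
    sensitivity both 0) is 0.
    """
    report = MetricsReport(cm=cm, group=group)
    if cm.tp + cm.fn > 0:
        report.sensitivity = 100.0 * cm.tp / (cm.tp + cm.fn)
    else:
        report.undefined["sensitivity"] = "no positive ground-truth segments (TP+FN=0)"
    if cm.tn + cm.fp > 0:
        report.specificity = 100.0 * cm.tn / (cm.tn + cm.fp)
    else:
        report.undefined["specificity"] = "no negative ground-truth segments (TN+FP=0)"
    if cm.tp + cm.fp > 0:
        report.precision = 100.0 * cm.tp / (cm.tp + cm.fp)
    else:
        report.undefined["precision"] = "no positive predictions (TP+FP=0)"
    if report.precision is not None and report.sensitivity is not None:
        p, s = report.precision, report.sensitivity
        report.f1 = 2 * p * s / (p + s) if (p + s) > 0 else 0.0
    else:
        report.undefined["f1"] = "precision or sensitivity undefined"
    return report


def grouped_metrics(
    df: pd.DataFrame, grouping: str = "subject"
) -> list[MetricsReport]:
    """Per-subject or per-category confusion matrices and metric reports.

    ``df`` needs columns ``y_true``, ``y_pred``, ``subject_id`` and (for
    category grouping) ``category``. Group matrices sum exactly to the
    overall matrix. Groups with undefined sensitivity (zero cough
    segments) are still returned, flagged, and a reason is logged so
    summaries can exclude them explicitly.
    """
    key = {"subject": "subject_id", "category": "category"}.get(grouping)
    if key is None:
        raise ValueError("grouping must be 'subject' or 'category'")
    reports = []
    for group, sub in df.groupby(key, sort=True):
        cm = ConfusionMatrix.from_predictions(sub["y_true"], sub["y_pred"])
        rep = metrics(cm, group=str(group))
        if "sensitivity" in rep.undefined:
            logger.info(
                "%s %r excluded from sensitivity/F1 summaries: %s",
                grouping, group, rep.undefined["sensitivity"],
            )
        reports.append(rep)
    return reports


def category_summary(per_subject: list[MetricsReport]) -> dict[str, float | None]:
    """Overall, median, IQR and SD of per-subject F1 within one category.

    The overall value pools the subjects' confusion counts; the
    distributional statistics are over defined per-subject F1 values only
    (zero-cough subjects are excluded, with their exclusion visible in
    ``n_excluded``).
    """
    pooled = ConfusionMatrix(0, 0, 0, 0)
    for rep in per_subject:
        pooled = pooled + rep.cm
    f1s = np.array([r.f1 for r in per_subject if r.f1 is not None], dtype=float)
    out: dict[str, float | None] = {
        "n_subjects": len(per_subject),
        "n_excluded": len(per_subject) - len(f1s),
        "overall_f1": metrics(pooled).f1,
    }
    if len(f1s):
        q1, med, q3 = np.percentile(f1s, [25, 50, 75])
        out.update(
            median_f1=float(med),
            iqr_low=float(q1),
            iqr_high=float(q3),
            sd_f1=float(np.std(f1s, ddof=1)) if len(f1s) > 1 else 0.0,
        )
    else:
        out.update(median_f1=None, iqr_low=None, iqr_high=None, sd_f1=None)
    return out


def kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    train_fn,
    k: int = 5,
    mode: str = "sample_based",
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Seeded k-fold cross-validation at sample or subject granularity.

    ``train_fn(X_train, y_train, X_test) -> scores in [0, 1]`` runs one
    fold. ``sample_based`` shuffles individual segments into near-equal
    folds; when ``groups`` (subject ids) are supplied and a subject spans
    folds, a data-leakage warning is emitted — highly similar segments
    from the same subject then sit on both sides of the fold boundary,
    inflating scores. ``subject_based`` uses grouped folds instead.

    Returns a per-fold F1 table; ``attrs`` carries mean and SD.
    """
    y = np.asarray(y, dtype=int)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(y):
        raise ValueError(f"k={k} exceeds sample count {len(y)}")
    if mode == "sample_based":
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(X)
        if groups is not None and len(np.unique(groups)) < len(y):
            warnings.warn(
                "sample-based folds place segments of the same subject in "
                "both training and evaluation folds, introducing a mild "
                "degree of data leakage",
                stacklevel=2,
            )
    elif mode == "subject_based":
        if groups is None:
            raise ValueError("subject_based mode requires groups")
        splitter = GroupKFold(n_splits=k)
        split_iter = splitter.split(X, y, groups)
    else:
        raise ValueError("mode must be 'sample_based' or 'subject_based'")

    rows = []
    for fold, (tr, te) in enumerate(split_iter):
        scores = np.asarray(train_fn(X[tr], y[tr], X[te]))
        cm = ConfusionMatrix.from_predictions(y[te], (scores >= 0.5).astype(int))
        rep = metrics(cm)
        rows.append({"fold": fold, "f1": rep.f1, "n_test": len(te)})
    df = pd.DataFrame(rows)
    defined = df["f1"].dropna().astype(float)
    df.attrs["mean_f1"] = float(defined.mean()) if len(defined) else None
    df.attrs["sd_f1"] = (
        float(defined.std(ddof=1)) if len(defined) > 1 else 0.0
    )
    return df


def metrics_table(reports: list[MetricsReport]) -> pd.DataFrame:
    """Flatten reports into a CSV-ready table (counts + rounded metrics)."""
    rows = []
    for rep in reports:
        row = {
            "group": rep.group,
            "tp": rep.cm.tp, "fp": rep.cm.fp, "tn": rep.cm.tn, "fn": rep.cm.fn,
        }
        row.update(rep.rounded())
        row["undefined"] = ";".join(sorted(rep.undefined)) or ""
        rows.append(row)
    return pd.DataFrame(rows)
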