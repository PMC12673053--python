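"""Class-weighted training of a pluggable spectrogram-image classifier.

The training regime is fixed: AdamW (beta1 0.9, beta2 0.999, eps 1e-8),
batch size 128, peak learning rate 5e-5 reached by a linear warm-up over
the first 10% of total steps then decayed to zero on a cosine schedule,
at most 20 epochs with patience-5 early stopping and best-checkpoint
restore, and class-weighted cross-entropy with ``w_i = N / (2 * N_i)`` so
the rare cough class carries the same total loss mass as the dominant
non-cough class. Weight decay is 0.001 for full-scale runs and 0.01 for
the pilot sweep.

Backends implement a small contract (feature extraction from 224x224x3
images, parameter init, per-batch gradient step, score prediction, state
snapshot) so the image classifier is swappable. The reference desk-scale
backend is a logistic model on block-averaged grayscale pixels that trains
on a CPU in minutes; larger pretrained vision backends can be plugged in
through the same contract.

The two-stage protocol is: a pilot sweep training one model per
spectrogram configuration on a ~10% subset drawn from the same underlying
events (so ranking differences reflect the spectrogram settings, not data
variation), ranked by test F1; then a full-scale run with the winning
configuration.
"""

from __future__ import annotations

import abc
import math
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.utils.validation import check_is_fitted

from .evaluation import ConfusionMatrix, metrics
from .spectrogram import SpectrogramConfig


@dataclass(frozen=True)
class ClassWeights:
    """Loss weights equalising total class mass: ``w_i = N / (2 * N_i)``."""

    w_cough: float
    w_non_cough: float
    n_total: int
    n_cough: int
    n_non_cough: int


def compute_class_weights(n_cough: int, n_non_cough: int) -> ClassWeights:
    """Inverse-frequency class weights for the binary cough task.

    Raises if either class is absent (the weights are then undefined).
    """
    if n_cough <= 0 or n_non_cough <= 0:
        raise ValueError(
            f"both classes must be present; got cough={n_cough}, "
            f"non_cough={n_non_cough}"
        )
    n = n_cough + n_non_cough
    return ClassWeights(
        w_cough=n / (2.0 * n_cough),
        w_non_cough=n / (2.0 * n_non_cough),
        n_total=n,
        n_cough=n_cough,
        n_non_cough=n_non_cough,
    )


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the fixed training regime (all overridable)."""

    batch_size: int = 128
    lr_peak: float = 5e-5
    warmup_fraction: float = 0.1
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.001
    max_epochs: int = 20
    patience: int = 5
    monitor: str = "f1"  # "f1" (default) or "loss"
    seed: int = 0

    def pilot(self) -> "TrainConfig":
        """The pilot-stage variant (stronger weight decay, 0.01)."""
        return replace(self, weight_decay=0.01)


def lr_at_step(step: int, total_steps: int, config: TrainConfig) -> float:
    """Learning rate at a global step: linear warm-up then cosine decay.

    Ramps 0 -> ``lr_peak`` over the first ``warmup_fraction`` of
    ``total_steps``, then follows
    ``lr_peak * 0.5 * (1 + cos(pi * t))`` where ``t`` traverses the decay
    phase, reaching exactly zero at the final step. Continuous at the
    junction and non-negative everywhere.
    """
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    warmup = config.warmup_fraction * total_steps
    if step <= warmup:
        return config.lr_peak * (step / warmup if warmup > 0 else 1.0)
    t = (step - warmup) / (total_steps - warmup)
    return config.lr_peak * 0.5 * (1.0 + math.cos(math.pi * t))


class AdamW:
    """Decoupled-weight-decay Adam over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], config: TrainConfig):
        self.params = params
        self.config = config
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        c = self.config
        self.t += 1
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            m_hat = self.m[k] / (1 - c.beta1**self.t)
            v_hat = self.v[k] / (1 - c.beta2**self.t)
            p -= lr * (m_hat / (np.sqrt(v_hat) + c.eps) + c.weight_decay * p)


class ClassifierBackend(abc.ABC):
    """Contract for pluggable image classifiers (input 224x224x3 uint8).

    A backend is stateless across runs given a seed: constructing, fitting
    and predicting with the same inputs and seed reproduces identical
    scores.
    """

    @abc.abstractmethod
    def prepare(self, images: np.ndarray) -> np.ndarray:
        """Turn images (n, 224, 224, 3) into the backend's feature matrix."""

    @abc.abstractmethod
    def init(self, n_features: int, rng: np.random.Generator) -> None:
        """Initialise trainable state."""

    @abc.abstractmethod
    def step_batch(
        self, features: np.ndarray, y: np.ndarray, sample_weight: np.ndarray,
        lr: float,
    ) -> float:
        """One weighted-cross-entropy gradient step; returns the batch loss."""

    @abc.abstractmethod
    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        """Cough-class probabilities in [0, 1] for prepared features."""

    @abc.abstractmethod
    def get_state(self) -> dict:
        """Deep copy of trainable state (for best-checkpoint restore)."""

    @abc.abstractmethod
    def set_state(self, state: dict) -> None:
        """Restore a snapshot from :meth:`get_state`."""


class PixelLogisticBackend(ClassifierBackend):
    """Desk-scale reference backend: logistic model on downsampled pixels.

    Each RGB channel is block-averaged to ``feature_size x feature_size``
    (224 must be divisible by it) and centred; the channels are kept
    separate because the jet colormap is not monotone in luminance, so a
    grayscale average would destroy the intensity ordering. A single
    linear layer with sigmoid output is trained by the shared AdamW loop;
    it fits on one CPU in well under a minute at the problem sizes used
    here. Note the peak learning rate appropriate for a raw linear model
    is orders of magnitude larger than for fine-tuning a pretrained
    transformer; pass a ``TrainConfig`` with ``lr_peak`` around 1e-2.
    """

    def __init__(self, feature_size: int = 28):
        if 224 % feature_size != 0:
            raise ValueError("feature_size must divide 224")
        self.feature_size = feature_size
        self.params: dict[str, np.ndarray] | None = None
        self._opt: AdamW | None = None
        self._config: TrainConfig | None = None

    def prepare(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images)
        if images.ndim != 4 or images.shape[1:] != (224, 224, 3):
            raise ValueError(
                f"expected (n, 224, 224, 3) images, got {images.shape}"
            )
        x = images.astype(np.float64) / 255.0
        k = 224 // self.feature_size
        pooled = x.reshape(
            len(x), self.feature_size, k, self.feature_size, k, 3
        ).mean(axis=(2, 4))
        flat = pooled.reshape(len(x), -1)
        return flat - flat.mean(axis=1, keepdims=True)

    def init(self, n_features: int, rng: np.random.Generator) -> None:
        self.params = {
            "W": rng.normal(0.0, 0.01, size=n_features),
            "b": np.zeros(1),
        }
        self._opt = None

    def configure_optimizer(self, config: TrainConfig) -> None:
        assert self.params is not None
        self._config = config
        self._opt = AdamW(self.params, config)

    def _logits(self, F: np.ndarray) -> np.ndarray:
        assert self.params is not None
        return F @ self.params["W"] + self.params["b"][0]

    def step_batch(self, features, y, sample_weight, lr) -> float:
        assert self._opt is not None
        z = self._logits(features)
        p = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-12
        losses = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        loss = float(np.mean(sample_weight * losses))
        dz = sample_weight * (p - y) / len(y)
        grads = {
            "W": features.T @ dz,
            "b": np.array([dz.sum()]),
        }
        self._opt.step(grads, lr)
        return loss

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self._logits(features)))

    def get_state(self) -> dict:
        assert self.params is not None
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict) -> None:
        assert self.params is not None
        for k in self.params:
            self.params[k][...] = state[k]


def _monitor_value(
    backend: ClassifierBackend,
    F_val: np.ndarray,
    y_val: np.ndarray,
    w_val: np.ndarray,
    monitor: str,
) -> tuple[float, float, float]:
    """Validation (monitored value, f1, weighted loss); larger monitored
    value is better (loss is negated)."""
    p = backend.predict_scores(F_val)
    eps = 1e-12
    losses = -(y_val * np.log(p + eps) + (1 - y_val) * np.log(1 - p + eps))
    loss = float(np.mean(w_val * losses))
    pred = (p >= 0.5).astype(int)
    cm = ConfusionMatrix.from_predictions(y_val, pred)
    rep = metrics(cm)
    f1 = rep.f1 if rep.f1 is not None else 0.0
    value = f1 if monitor == "f1" else -loss
    return value, f1, loss


def train(
    backend: ClassifierBackend,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
    *,
    train_subjects: np.ndarray | None = None,
    val_subjects: np.ndarray | None = None,
    prepared: bool = False,
) -> tuple[ClassifierBackend, pd.DataFrame]:
    """Run the class-weighted training loop with early stopping.

    Per epoch the validation monitor (F1 by default, weighted loss if
    ``config.monitor == "loss"``) is recorded; training stops after
    ``patience`` epochs without improvement and the best checkpoint is
    restored. When subject arrays are given, subject-disjointness of the
    two sets is asserted (identity leakage guard).

    Returns the fitted backend and a per-epoch history table.
    """
    if len(X_train) == 0:
        raise ValueError("empty training set")
    if train_subjects is not None and val_subjects is not None:
        shared = set(np.unique(train_subjects)) & set(np.unique(val_subjects))
        if shared:
            raise ValueError(f"train/val sets share subjects: {sorted(shared)}")
    y_train = np.asarray(y_train, dtype=int)
    y_val = np.asarray(y_val, dtype=int)
    cw = compute_class_weights(int(y_train.sum()), int((1 - y_train).sum()))
    w_train = np.where(y_train == 1, cw.w_cough, cw.w_non_cough)
    # validation loss uses the same weighting so the monitored loss is
    # comparable to the training objective
    w_val = np.where(y_val == 1, cw.w_cough, cw.w_non_cough)

    F_train = X_train if prepared else backend.prepare(X_train)
    F_val = X_val if prepared else backend.prepare(X_val)
    rng = np.random.default_rng(config.seed)
    backend.init(F_train.shape[1], rng)
    if isinstance(backend, PixelLogisticBackend):
        backend.configure_optimizer(config)

    steps_per_epoch = max(1, math.ceil(len(F_train) / config.batch_size))
    total_steps = steps_per_epoch * config.max_epochs
    best_value = -np.inf
    best_state = backend.get_state()
    best_epoch = 0
    bad_epochs = 0
    history = []
    step = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(F_train))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            lr = lr_at_step(step, total_steps, config)
            epoch_loss += backend.step_batch(
                F_train[idx], y_train[idx], w_train[idx], lr
            )
            step += 1
        value, val_f1, val_loss = _monitor_value(
            backend, F_val, y_val, w_val, config.monitor
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / steps_per_epoch,
                "val_f1": val_f1,
                "val_loss": val_loss,
                "monitored": value,
            }
        )
        if value > best_value + 1e-12:
            best_value = value
            best_state = backend.get_state()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    backend.set_state(best_state)
    hist = pd.DataFrame(history)
    hist.attrs["best_epoch"] = best_epoch
    hist.attrs["class_weights"] = cw
    return backend, hist


# ---------------------------------------------------------------------------
# sklearn-style estimator


class WeightedSegmentClassifier(BaseEstimator, ClassifierMixin):
    """Cough/non-cough spectrogram-image classifier with class weighting.

    Parameters
    ----------
    backend : str or ClassifierBackend
        ``"logistic"`` for the desk-scale reference backend, or any object
        implementing :class:`ClassifierBackend`.
    feature_size : int
        Downsampling of the reference backend (grayscale block mean to
        ``feature_size x feature_size``).
    validation_fraction : float
        Held-out fraction used for early stopping when :meth:`fit` is not
        given an explicit validation set; split subject-wise when
        ``groups`` are passed.
    monitor : str
        Early-stopping monitor: validation ``"f1"`` (default) or ``"loss"``.

    Other parameters mirror :class:`TrainConfig`.
    """

    def __init__(
        self,
        backend: str | ClassifierBackend = "logistic",
        feature_size: int = 28,
        batch_size: int = 128,
        lr_peak: float = 5e-5,
        weight_decay: float = 0.001,
        max_epochs: int = 20,
        patience: int = 5,
        monitor: str = "f1",
        validation_fraction: float = 0.2,
        seed: int = 0,
    ):
        self.backend = backend
        self.feature_size = feature_size
        self.batch_size = batch_size
        self.lr_peak = lr_peak
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.monitor = monitor
        self.validation_fraction = validation_fraction
        self.seed = seed

    def _make_backend(self) -> ClassifierBackend:
        if self.backend == "logistic":
            return PixelLogisticBackend(self.feature_size)
        if isinstance(self.backend, ClassifierBackend):
            return self.backend
        raise ValueError(f"unknown backend {self.backend!r}")

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size,
            lr_peak=self.lr_peak,
            weight_decay=self.weight_decay,
            max_epochs=self.max_epochs,
            patience=self.patience,
            monitor=self.monitor,
            seed=self.seed,
        )

    def fit(self, X, y, validation_data=None, groups=None):
        """Fit on images ``X`` (n, 224, 224, 3) and labels ``y`` (0/1).

        ``validation_data=(X_val, y_val)`` supplies the early-stopping set
        explicitly; otherwise ``validation_fraction`` is held out, grouped
        by ``groups`` (subject ids) when given so the monitor set stays
        subject-disjoint.
        """
        y = np.asarray(y, dtype=int)
        self.classes_ = np.array([0, 1])
        backend = self._make_backend()
        if validation_data is not None:
            X_tr, y_tr = X, y
            X_va, y_va = validation_data
        elif groups is not None:
            uniq = np.unique(groups)
            rng = np.random.default_rng(self.seed)
            n_val = max(1, int(round(self.validation_fraction * len(uniq))))
            val_subjects = set(rng.permutation(uniq)[:n_val])
            mask = np.array([g in val_subjects for g in groups])
            X_tr, y_tr, X_va, y_va = X[~mask], y[~mask], X[mask], y[mask]
        else:
            X_tr, X_va, y_tr, y_va = train_test_split(
                X, y, test_size=self.validation_fraction,
                random_state=self.seed, stratify=y,
            )
        self.backend_, self.history_ = train(
            backend, X_tr, y_tr, X_va, y_va, self._train_config()
        )
        self.class_weights_ = self.history_.attrs["class_weights"]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "backend_")
        p = self.backend_.predict_scores(self.backend_.prepare(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# stage-1 pilot sweep


def subset_sample(
    labels: np.ndarray,
    source_events: np.ndarray,
    subject_ids: np.ndarray,
    fraction: float,
    seed: int,
) -> np.ndarray:
    """Boolean mask selecting a ~``fraction`` subset anchored on events.

    Cough segments are sampled at the *event* level — a per-subject seeded
    draw of annotated events, the same events for every spectrogram
    configuration — and every cough segment tied to a chosen event is kept.
    Non-cough segments are sampled per subject at the segment level with a
    subject-derived seed.
    """
    mask = np.zeros(len(labels), dtype=bool)
    for subject in np.unique(subject_ids):
        sub = subject_ids == subject
        sub_rng = np.random.default_rng(
            (seed * 1_000_003 + zlib.crc32(str(subject).encode())) % (2**31)
        )
        events = np.unique(source_events[sub & (labels == 1)])
        events = events[events >= 0]
        if len(events):
            n_keep = max(1, int(round(fraction * len(events))))
            chosen = set(sub_rng.permutation(events)[:n_keep].tolist())
            keep_pos = sub & (labels == 1) & np.isin(
                source_events, np.array(sorted(chosen))
            )
            mask |= keep_pos
        neg_idx = np.flatnonzero(sub & (labels == 0))
        n_neg = max(1, int(round(fraction * len(neg_idx))))
        mask[sub_rng.permutation(neg_idx)[:n_neg]] = True
    return mask


def pilot_sweep(
    per_config_data: dict[str, dict[str, dict[str, np.ndarray]]],
    train_config: TrainConfig | None = None,
    backend_factory=None,
) -> pd.DataFrame:
    """Train and score one model per spectrogram configuration.

    ``per_config_data`` maps config id -> split name ("train"/"validation"/
    "test") -> ``{"X": images, "y": labels}``; the caller is responsible
    for drawing every configuration's samples from the same underlying
    events (see :func:`subset_sample` and the pipeline helpers). Returns
    one row per configuration with train/validation/test F1, the
    train-test gap, test precision and test recall; the best configuration
    by test F1 is flagged in the ``best`` column.
    """
    train_config = (train_config or TrainConfig()).pilot()
    backend_factory = backend_factory or (lambda: PixelLogisticBackend())
    rows = []
    for config_id, splits in per_config_data.items():
        backend = backend_factory()
        fitted, _ = train(
            backend,
            splits["train"]["X"], splits["train"]["y"],
            splits["validation"]["X"], splits["validation"]["y"],
            train_config,
        )
        row: dict[str, object] = {"config_id": config_id}
        for name in ("train", "validation", "test"):
            p = fitted.predict_scores(fitted.prepare(splits[name]["X"]))
            cm = ConfusionMatrix.from_predictions(
                splits[name]["y"], (p >= 0.5).astype(int)
            )
            rep = metrics(cm)
            row[f"{name}_f1"] = rep.f1
            if name == "test":
                row["test_precision"] = rep.precision
                row["test_recall"] = rep.sensitivity
        row["train_test_gap"] = (
            (row["test_f1"] - row["train_f1"])
            if row["test_f1"] is not None and row["train_f1"] is not None
            else None
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    test_f1 = df["test_f1"].astype(float)
    df["best"] = test_f1 == test_f1.max()
    return df


def aggregate_pilot(df: pd.DataFrame, by: str) -> pd.DataFrame:
    """Mean pilot metrics grouped by ``"duration"``, ``"frame"`` or ``"hop"``.

    ``hop`` groups by hop fraction of the frame (50% vs 25%), matching the
    way sweep results are conventionally summarised.
    """
    parts = df["config_id"].str.split("_", expand=True).astype(int)
    if by == "duration":
        key = parts[0].astype(str) + " ms"
    elif by == "frame":
        key = parts[1].astype(str)
    elif by == "hop":
        key = (100 * parts[2] // parts[1]).astype(str) + "%"
    else:
        raise ValueError("by must be 'duration', 'frame' or 'hop'")
    cols = [
        "train_f1", "validation_f1", "test_f1", "train_test_gap",
        "test_precision", "test_recall",
    ]
    out = df.assign(group=key).groupby("group", sort=True)[cols].mean()
    return out.reset_index()
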