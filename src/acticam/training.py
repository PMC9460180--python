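"""Training and evaluation: BCE loss, Adam, reduce-on-plateau LR, k-fold CV.

Each epoch draws a fresh sample of training windows, updates the network
once per 64-window batch with Adam, applies the plateau rule to the mean
epoch training loss (divide the learning rate by 10 after 10 consecutive
epochs without improvement), and evaluates accuracy and F-score on a fixed
deterministic set of validation windows.  Training stops at ``max_epochs``
or when the learning rate falls below ``min_lr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .models import Model, ModelConfig, build_model
from .nn.optim import Adam
from .prep import DatasetSpec, DriveRecord, Fold, LabelledWindow, apply_task_exclusions, enumerate_windows, make_folds, sample_random_window

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 64
    initial_lr: float = 1e-4
    lr_factor: float = 10.0
    patience: int = 10
    improvement_tol: float = 1e-4
    max_epochs: int = 100
    windows_per_epoch: int | None = None  # default: n_drives * (drive_len // window_len)
    min_lr: float = 1e-7
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")
        if self.initial_lr <= 0 or self.min_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.lr_factor <= 1:
            raise ValueError("lr_factor must exceed 1")


@dataclass
class EpochLog:
    epoch: int
    train_loss: float
    val_accuracy: float
    val_f_score: float
    lr: float


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.total

    @property
    def f_score(self) -> float:
        precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        if precision + recall == 0.0:
            return 0.0
        return 2.0 * precision * recall / (precision + recall)


@dataclass
class FoldResult:
    fold: int
    accuracy: float
    f_score: float
    confusion: ConfusionMatrix
    epoch_logs: list[EpochLog]
    val_logits: np.ndarray
    val_labels: np.ndarray
    val_participants: list[str]


@dataclass
class CVSummary:
    task: str
    architecture: str
    folds: list[FoldResult]
    mean_accuracy: float
    sd_accuracy: float
    mean_f_score: float
    sd_f_score: float


# ---------------------------------------------------------------------------
# Loss and schedule
# ---------------------------------------------------------------------------


def bce_loss(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of sigmoid(logit) against {0,1} labels.

    Computed in the standard numerically stable form
    ``max(z, 0) - z*y + log(1 + exp(-|z|))``.
    """
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if logits.shape != labels.shape:
        raise ValueError("logits and labels must have equal length")
    if logits.size == 0:
        raise ValueError("cannot compute the loss of an empty batch")
    per = np.maximum(logits, 0.0) - logits * labels + np.log1p(np.exp(-np.abs(logits)))
    return float(per.mean())


def bce_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(logits) = (sigmoid(z) - y) / batch."""
    z = np.asarray(logits, dtype=np.float64)
    return (_sigmoid(z) - labels) / z.size


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass
class LRScheduleState:
    lr: float
    factor: float = 10.0
    patience: int = 10
    improvement_tol: float = 1e-4
    min_lr: float = 1e-7
    best_loss: float = np.inf
    stall: int = 0
    exhausted: bool = False  # set when a reduction would cross min_lr

    def step(self, train_loss: float) -> float:
        """Update on one epoch's training loss; returns the (possibly reduced) lr."""
        if train_loss < self.best_loss - self.improvement_tol:
            self.best_loss = train_loss
            self.stall = 0
        else:
            self.stall += 1
            if self.stall >= self.patience:
                reduced = self.lr / self.factor
                if reduced < self.min_lr:
                    self.exhausted = True
                self.lr = max(reduced, self.min_lr)
                self.stall = 0
        return self.lr


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def predict_logits(model: Model, windows: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = np.empty(len(windows), dtype=np.float64)
    for i in range(0, len(windows), batch_size):
        out[i : i + batch_size] = model.forward(windows[i : i + batch_size], train=False)
    return out


def confusion_from_predictions(pred: np.ndarray, labels: np.ndarray) -> ConfusionMatrix:
    pred = np.asarray(pred).astype(bool)
    labels = np.asarray(labels).astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
        tn=int(np.sum(~pred & ~labels)),
    )


def evaluate(model: Model, windows: np.ndarray, labels: np.ndarray, threshold: float = 0.5):
    """Accuracy (%), F-score and confusion matrix at the given sigmoid threshold."""
    if len(windows) == 0:
        raise ValueError("cannot evaluate on an empty validation set")
    logits = predict_logits(model, windows)
    cm = confusion_from_predictions(_sigmoid(logits) >= threshold, labels)
    return cm.accuracy, cm.f_score, cm, logits


# ---------------------------------------------------------------------------
# Fold data plumbing
# ---------------------------------------------------------------------------


@dataclass
class FoldData:
    """Training source and fixed validation windows for one fold.

    Window-level folds sample training windows from the fold's training pool
    (so the held-out windows themselves are never trained on); participant-
    level folds sample genuine random offsets from the training
    participants' drives.
    """

    fold: int
    task: str
    window_length: int
    train_windows: list[LabelledWindow] | None
    train_drives: list[DriveRecord] | None
    val_windows: list[LabelledWindow]
    n_train_drives: int

    def sample_training_batch(self, size: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        if self.train_drives is not None:
            drives = rng.integers(0, len(self.train_drives), size)
            wins = [sample_random_window(self.train_drives[i], self.task, self.window_length, rng) for i in drives]
        else:
            idx = rng.integers(0, len(self.train_windows), size)
            wins = [self.train_windows[i] for i in idx]
        x = np.stack([w.values for w in wins]).astype(np.float32)
        y = np.array([w.label for w in wins], dtype=np.float64)
        return x, y

    def val_arrays(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        x = np.stack([w.values for w in self.val_windows]).astype(np.float32)
        y = np.array([w.label for w in self.val_windows], dtype=np.float64)
        return x, y, [w.participant_id for w in self.val_windows]


class TaskDataset:
    """Drives, enumerated windows and CV folds for one classification task."""

    def __init__(self, drives: list[DriveRecord], spec: DatasetSpec):
        self.spec = spec
        self.drives = apply_task_exclusions(drives, spec.task)
        if not self.drives:
            raise ValueError("no drives remain after task exclusions")
        self.windows = [
            w for d in self.drives for w in enumerate_windows(d, spec.task, spec.window_length, spec.eval_stride)
        ]
        if spec.split_mode == "window_level":
            self._folds = make_folds(self.windows, spec.k, "window_level", spec.seed)
        else:
            participants = sorted({d.participant_id for d in self.drives})
            label_of = {d.participant_id: d.label(spec.task) for d in self.drives}
            self._folds = make_folds(
                participants, spec.k, "participant_level", spec.seed, labels=[label_of[p] for p in participants]
            )

    @property
    def k(self) -> int:
        return self.spec.k

    def fold_data(self, i: int) -> FoldData:
        fold = self._folds[i]
        if self.spec.split_mode == "window_level":
            return FoldData(
                fold=i,
                task=self.spec.task,
                window_length=self.spec.window_length,
                train_windows=fold.train_units,
                train_drives=None,
                val_windows=fold.val_units,
                n_train_drives=len(self.drives),
            )
        train_p, val_p = set(fold.train_units), set(fold.val_units)
        train_drives = [d for d in self.drives if d.participant_id in train_p]
        val_windows = [w for w in self.windows if w.participant_id in val_p]
        return FoldData(
            fold=i,
            task=self.spec.task,
            window_length=self.spec.window_length,
            train_windows=None,
            train_drives=train_drives,
            val_windows=val_windows,
            n_train_drives=len(train_drives),
        )

    def folds(self) -> list[Fold]:
        return self._folds


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------


def default_windows_per_epoch(n_drives: int, drive_samples: int, window_length: int) -> int:
    return max(n_drives * max(drive_samples // window_length, 1), 1)


def train_fold(model_config: ModelConfig, fold_data: FoldData, train_config: TrainConfig) -> tuple[FoldResult, Model]:
    """Train one fold to completion and evaluate it on its validation windows."""
    rng = np.random.default_rng(train_config.seed)
    model = build_model(model_config)
    optimizer = Adam(model.params(), lr=train_config.initial_lr)
    schedule = LRScheduleState(
        lr=train_config.initial_lr,
        factor=train_config.lr_factor,
        patience=train_config.patience,
        improvement_tol=train_config.improvement_tol,
        min_lr=train_config.min_lr,
    )
    x_val, y_val, val_participants = fold_data.val_arrays()

    wpe = train_config.windows_per_epoch
    if wpe is None:
        drive_samples = (
            len(fold_data.train_drives[0].signal)
            if fold_data.train_drives
            else fold_data.window_length * max(len(fold_data.train_windows) // max(fold_data.n_train_drives, 1), 1)
        )
        wpe = default_windows_per_epoch(fold_data.n_train_drives, drive_samples, fold_data.window_length)

    logs: list[EpochLog] = []
    for epoch in range(train_config.max_epochs):
        losses = []
        remaining = wpe
        while remaining > 0:
            size = min(train_config.batch_size, remaining)
            remaining -= size
            x, y = fold_data.sample_training_batch(size, rng)
            logits = model.forward(x, train=True)
            loss = bce_loss(logits, y)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            optimizer.zero_grad()
            model.backward(bce_grad(logits, y).astype(np.float32))
            optimizer.lr = schedule.lr
            optimizer.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        lr_after = schedule.step(epoch_loss)
        acc, f1, _, _ = evaluate(model, x_val, y_val, train_config.threshold)
        logs.append(EpochLog(epoch=epoch, train_loss=epoch_loss, val_accuracy=acc, val_f_score=f1, lr=lr_after))
        logger.info("fold %d epoch %d loss %.4f acc %.1f%% lr %g", fold_data.fold, epoch, epoch_loss, acc, lr_after)
        if schedule.exhausted:
            break

    acc, f1, cm, logits = evaluate(model, x_val, y_val, train_config.threshold)
    result = FoldResult(
        fold=fold_data.fold,
        accuracy=acc,
        f_score=f1,
        confusion=cm,
        epoch_logs=logs,
        val_logits=logits,
        val_labels=y_val.astype(int),
        val_participants=val_participants,
    )
    return result, model


def cross_validate(
    model_config: ModelConfig, dataset: TaskDataset, train_config: TrainConfig, return_models: bool = False
):
    """Run every fold and summarize accuracy / F-score as mean +- SD."""
    results, models = [], []
    for i in range(dataset.k):
        fold_cfg = TrainConfig(**{**train_config.__dict__, "seed": (train_config.seed + 7919 * i) % 2**31})
        model_cfg = ModelConfig(**{**model_config.__dict__, "seed": (model_config.seed + 104729 * i) % 2**31})
        result, model = train_fold(model_cfg, dataset.fold_data(i), fold_cfg)
        results.append(result)
        if return_models:
            models.append(model)
    accs = np.array([r.accuracy for r in results])
    f1s = np.array([r.f_score for r in results])
    summary = CVSummary(
        task=dataset.spec.task,
        architecture=model_config.architecture,
        folds=results,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)) if len(accs) > 1 else 0.0,
        mean_f_score=float(f1s.mean()),
        sd_f_score=float(f1s.std(ddof=1)) if len(f1s) > 1 else 0.0,
    )
    return (summary, models) if return_models else summary


def plot_learning_curves(results: list[FoldResult], path) -> None:
    """F-score and ln(training loss) per epoch for every fold, side by side."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_f, ax_l) = plt.subplots(1, 2, figsize=(10, 4))
    for r in results:
        epochs = [log.epoch for log in r.epoch_logs]
        ax_f.plot(epochs, [log.val_f_score for log in r.epoch_logs], label=f"fold {r.fold}")
        ax_l.plot(epochs, [np.log(max(log.train_loss, 1e-12)) for log in r.epoch_logs], label=f"fold {r.fold}")
    ax_f.set_xlabel("epoch")
    ax_f.set_ylabel("validation F-score")
    ax_l.set_xlabel("epoch")
    ax_l.set_ylabel("ln training loss")
    ax_f.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
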