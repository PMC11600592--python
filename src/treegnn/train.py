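"""Training loop, target standardization, early stopping, and evaluation.

Training uses Adam with the conventional bias-corrected moment estimates.
Early stopping monitors validation accuracy for classification and negative
validation loss for regression, requiring strict improvement; the
best-validation weights are restored at the end.  Metrics follow the field's
conventions: RMSE and the coefficient of determination R^2 = 1 - SS_res /
SS_tot for regression (reported on the log scale when targets were
log-standardized), row-normalized confusion matrices, trapezoidal ROC AUC
and step-wise average precision for each declared binary contrast.
"""

from __future__ import annotations

import contextlib
import gc
import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .featurize import FeaturizedSequence
from .nn.model import Batch, LossSpec, TreeSequenceNet, collate, loss as compute_loss


# ---------------------------------------------------------------------------
# target standardization
# ---------------------------------------------------------------------------


@dataclass
class TargetStats:
    mean: np.ndarray
    sd: np.ndarray
    log_scale: bool

    @classmethod
    def fit(cls, values: np.ndarray, log_scale: bool) -> "TargetStats":
        v = np.atleast_2d(np.asarray(values, dtype=float))
        if log_scale:
            if np.any(v <= 0):
                raise ValueError("log-scaled targets must be positive")
            v = np.log(v)
        sd = v.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        return cls(mean=v.mean(axis=0), sd=sd, log_scale=log_scale)


def standardize_targets(values: np.ndarray, stats: TargetStats) -> np.ndarray:
    """z = (ln v - mu) / sigma when log-scaled, else (v - mu) / sigma."""
    v = np.asarray(values, dtype=float)
    if stats.log_scale:
        if np.any(v <= 0):
            raise ValueError("log-scaled targets must be positive")
        v = np.log(v)
    return (v - stats.mean) / stats.sd


def destandardize_targets(z: np.ndarray, stats: TargetStats) -> np.ndarray:
    """Inverse of standardize_targets (exact algebraic inverse)."""
    v = np.asarray(z, dtype=float) * stats.sd + stats.mean
    return np.exp(v) if stats.log_scale else v


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    learning_rate: float = 1e-5
    betas: tuple[float, float] = (0.9, 0.999)
    batch_size: int = 16
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0
    loss: LossSpec = field(default_factory=lambda: LossSpec("smooth_l1"))
    classification: bool = False
    shuffle: bool = True
    dtype: str = "float32"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max epochs")


class Adam:
    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_metric: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


@contextlib.contextmanager
def _gc_paused():
    """Suspend cyclic garbage collection inside the hot loop.

    The tape allocates thousands of container objects per batch; periodic
    generational scans of that graph dominate runtime.  The tape itself is
    acyclic, so reference counting reclaims it promptly without the
    collector.
    """
    was_enabled = gc.isenabled()
    gc.disable()
    try:
        yield
    finally:
        if was_enabled:
            gc.enable()
            gc.collect()


def _iter_batches(sequences, batch_size, rng, shuffle, dtype):
    order = np.arange(len(sequences))
    if shuffle:
        rng.shuffle(order)
    for lo in range(0, len(order), batch_size):
        idx = order[lo : lo + batch_size]
        yield collate([sequences[i] for i in idx], dtype=dtype)


def _predict_batches(model, sequences, batch_size, dtype):
    preds, targets = [], []
    model.eval()
    with _gc_paused():
        for lo in range(0, len(sequences), batch_size):
            batch = collate(sequences[lo : lo + batch_size], dtype=dtype)
            preds.append(model(batch).data.copy())
            if batch.targets is not None:
                targets.append(batch.targets)
    return np.concatenate(preds), (np.concatenate(targets) if targets else None)


def predict(model: TreeSequenceNet, sequences: Sequence[FeaturizedSequence], batch_size: int = 64) -> np.ndarray:
    dtype = model.out.weight.data.dtype
    preds, _ = _predict_batches(model, sequences, batch_size, dtype)
    return preds


def _batch_targets(batch: Batch, config: TrainConfig):
    t = batch.targets
    if t is None:
        raise ValueError("training split has unlabeled sequences")
    if config.classification:
        return t.reshape(-1).astype(np.int64)
    return t.reshape(t.shape[0], -1)


def train(
    model: TreeSequenceNet,
    train_set: Sequence[FeaturizedSequence],
    validation_set: Sequence[FeaturizedSequence],
    config: TrainConfig,
    callback: Callable[[int, TrainHistory], None] | None = None,
) -> TrainHistory:
    """Fit the model; returns the history with best weights restored.

    Deterministic given the seed and single-threaded numerics: batch order,
    initialization and every update depend only on (model init, seed).
    """
    if len(train_set) == 0 or len(validation_set) == 0:
        raise ValueError("empty train or validation split")
    dtype = np.dtype(config.dtype)
    model.astype(dtype)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate, betas=config.betas)
    history = TrainHistory()
    best_metric = -np.inf
    best_state = model.state_dict()
    epochs_since_best = 0

    for epoch in range(config.max_epochs):
        model.train()
        epoch_losses = []
        ctx = _gc_paused()
        ctx.__enter__()
        for batch in _iter_batches(train_set, config.batch_size, rng, config.shuffle, dtype):
            model.zero_grad()
            out = model(batch)
            l = compute_loss(out, _batch_targets(batch, config), config.loss)
            if not np.isfinite(l.data):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            l.backward()
            optimizer.step()
            epoch_losses.append(float(l.data))
        history.train_loss.append(float(np.mean(epoch_losses)))

        # validation
        model.eval()
        val_losses, correct, count = [], 0, 0
        for batch in _iter_batches(validation_set, config.batch_size, rng, False, dtype):
            out = model(batch)
            t = _batch_targets(batch, config)
            val_losses.append(float(compute_loss(out, t, config.loss).data))
            if config.classification:
                correct += int((out.data.argmax(axis=1) == t).sum())
                count += len(t)
        ctx.__exit__(None, None, None)
        val_loss = float(np.mean(val_losses))
        history.val_loss.append(val_loss)
        metric = (correct / count) if config.classification else -val_loss
        history.val_metric.append(metric)

        if metric > best_metric:
            best_metric = metric
            best_state = model.state_dict()
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if callback is not None:
            callback(epoch, history)
        if epochs_since_best >= config.patience:
            break
    history.stopped_epoch = len(history.train_loss) - 1
    model.load_state_dict(best_state)
    return history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


#: declared binary contrasts per classification task: name -> (positive
#: score from class posteriors, example subset mask from true labels)
TASK_CONTRASTS: dict[str, dict] = {
    "sweeps": {
        # class order: hard, hard-linked, soft, soft-linked, neutral
        "sweep_vs_unselected": {
            "positive_classes": (0, 2),
            "label_fn": lambda y: np.isin(y, (0, 2)).astype(int),
            "subset_fn": lambda y: np.ones_like(y, dtype=bool),
        },
        "hard_vs_soft": {
            "positive_classes": (0,),
            "label_fn": lambda y: (y == 0).astype(int),
            "subset_fn": lambda y: np.isin(y, (0, 2)),
        },
    },
    "introgression": {
        # class order: A->B, B->A, none
        "introgressed_vs_none": {
            "positive_classes": (0, 1),
            "label_fn": lambda y: np.isin(y, (0, 1)).astype(int),
            "subset_fn": lambda y: np.ones_like(y, dtype=bool),
        },
        "direction": {
            "positive_classes": (0,),
            "label_fn": lambda y: (y == 0).astype(int),
            "subset_fn": lambda y: np.isin(y, (0, 1)),
        },
    },
}


@dataclass
class EvalReport:
    task: str
    rmse: np.ndarray | None = None
    r_squared: np.ndarray | None = None
    confusion: np.ndarray | None = None
    roc_auc: dict = field(default_factory=dict)
    average_precision: dict = field(default_factory=dict)
    accuracy: float | None = None
    scores: np.ndarray | None = None

    def to_json(self) -> str:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        d = {k: conv(v) for k, v in asdict(self).items()}
        return json.dumps(d, indent=1)


def regression_metrics(predicted: np.ndarray, true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-target RMSE and R^2 = 1 - SS_res/SS_tot."""
    predicted = np.atleast_2d(predicted)
    true = np.atleast_2d(true)
    resid = predicted - true
    rmse = np.sqrt((resid**2).mean(axis=0))
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((true - true.mean(axis=0)) ** 2).sum(axis=0)
    return rmse, 1.0 - ss_res / ss_tot


def confusion_matrix(true: np.ndarray, predicted: np.ndarray, n_classes: int) -> np.ndarray:
    """Row-normalized confusion matrix (rows = true class, rows sum to 1)."""
    cm = np.zeros((n_classes, n_classes))
    for t, p in zip(true, predicted):
        cm[int(t), int(p)] += 1
    row_sums = cm.sum(axis=1, keepdims=True)
    return cm / np.where(row_sums == 0, 1.0, row_sums)


def evaluate(
    model: TreeSequenceNet,
    test_set: Sequence[FeaturizedSequence],
    task: str,
    target_stats: TargetStats | None = None,
    batch_size: int = 64,
) -> EvalReport:
    """Compute the task's metric suite on a held-out test set.

    Regression tasks report RMSE/R^2 on the standardized log scale (the
    natural units of the network's outputs, back-transformed once through
    the target sds); classification tasks report the row-normalized argmax
    confusion matrix plus ROC AUC and average precision for each contrast
    declared for the task.
    """
    dtype = model.out.weight.data.dtype
    preds, targets = _predict_batches(model, list(test_set), batch_size, dtype)
    if targets is None:
        raise ValueError("test set has no labels")
    report = EvalReport(task=task, scores=preds)
    if task in ("recombination", "demography"):
        true = targets.reshape(targets.shape[0], -1)
        if target_stats is not None:
            pred_log = preds * target_stats.sd + target_stats.mean
            true_log = true * target_stats.sd + target_stats.mean
        else:
            pred_log, true_log = preds, true
        report.rmse, report.r_squared = regression_metrics(pred_log, true_log)
        return report
    y = targets.reshape(-1).astype(int)
    n_classes = preds.shape[1]
    posts = _softmax(preds)
    report.confusion = confusion_matrix(y, preds.argmax(axis=1), n_classes)
    report.accuracy = float((preds.argmax(axis=1) == y).mean())
    for name, contrast in TASK_CONTRASTS.get(task, {}).items():
        subset = contrast["subset_fn"](y)
        labels = contrast["label_fn"](y)[subset]
        score = posts[np.ix_(subset, np.asarray(contrast["positive_classes"]))].sum(axis=1)
        if len(np.unique(labels)) < 2:
            raise ValueError(f"contrast {name!r}: test set has a single class")
        report.roc_auc[name] = float(np.clip(roc_auc_score(labels, score), 0.0, 1.0))
        report.average_precision[name] = float(
            np.clip(average_precision_score(labels, score), 0.0, 1.0)
        )
    return report
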