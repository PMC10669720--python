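"""Training loop and evaluation harness for the capsule network.

Training uses Adam on the margin loss (plus a small reconstruction
term), one of three learning-rate policies — plateau reduction
(multiply by a factor after a patience of stagnant validation epochs),
stepped decay, or fixed — and an overfitting guard that stops when the
validation margin loss drifts more than a configured fraction away from
the training loss.  Evaluation reports the confusion matrix at the
digitization threshold, the derived fractions (precision, recall,
specificity, accuracy, F1), and an ROC/AUC built from the positive-class
capsule length as the continuous score.

The positive class is "normal" throughout, matching the orientation of
the reference confusion matrix; pass ``positive_label=1`` to flip it.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .autodiff import Adam
from .capsnet import CapsNet
from .preprocess import MFCCSpectrum, NORMAL

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "ConfusionMatrix",
    "EvalReport",
    "SpectrumDataset",
    "fit",
    "lr_schedule",
    "evaluate",
    "metrics_from_confusion",
    "aggregate_by_recording",
]


@dataclass
class TrainConfig:
    """Hyperparameters; defaults reproduce the reference 5-s setup
    (learning rate 0.0025, 100 epochs, 5 routing iterations, Adam,
    plateau factor 0.15 with patience 3, early-stop gap 15%)."""

    learning_rate: float = 0.0025
    epochs: int = 100
    batch_size: int = 8
    lr_policy: str = "plateau"  # {"plateau", "decay", "fixed"}
    plateau_factor: float = 0.15
    plateau_patience: int = 3
    decay_initial: float = 0.005
    decay_factor: float = 0.1
    decay_interval: int = 30  # epochs between stepped decays
    early_stop_gap: float | None = 0.15
    early_stop_mode: str = "relative"  # or "absolute"
    restore_best: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 and self.learning_rate != 0.0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 < self.plateau_factor < 1.0):
            raise ValueError("plateau factor must be in (0, 1)")
        if self.lr_policy not in ("plateau", "decay", "fixed"):
            raise ValueError(f"unknown lr policy '{self.lr_policy}'")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with normal as the positive class: TP = normal predicted
    normal, TN = abnormal predicted abnormal."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    metrics: dict[str, float | None]
    roc: list[tuple[float, float]]  # (FPR, TPR) points
    auc: float | None

    def to_dict(self) -> dict:
        return {
            "confusion": asdict(self.confusion),
            "metrics": self.metrics,
            "auc": self.auc,
            "roc": self.roc,
        }


class SpectrumDataset:
    """Labeled spectra stacked into arrays: X (N, H, W, 1), y (N,)."""

    def __init__(self, X: np.ndarray, y: np.ndarray, ids: list[str] | None = None):
        self.X = np.asarray(X, dtype=np.float64)
        self.y = np.asarray(y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        self.ids = ids if ids is not None else [str(i) for i in range(len(self.y))]

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_spectra(cls, spectra: list[MFCCSpectrum]) -> "SpectrumDataset":
        if any(sp.label is None for sp in spectra):
            raise ValueError("all spectra must be labeled")
        X = np.stack([sp.values[:, :, None] for sp in spectra])
        y = np.array([sp.label for sp in spectra])
        return cls(X, y, ids=[sp.segment_id for sp in spectra])


def _onehot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    return np.eye(n_classes)[np.asarray(y, dtype=int)]


def lr_schedule(
    policy: str,
    epoch_history: list[dict],
    config: TrainConfig = TrainConfig(),
) -> float:
    """Learning rate for the *next* epoch given the history so far.

    plateau: multiply by `plateau_factor` each time the validation loss
    has not improved for `plateau_patience` consecutive epochs.
    decay: start at `decay_initial`, multiply by `decay_factor` every
    `decay_interval` epochs.  fixed: the initial rate, always.
    """
    if policy == "fixed":
        return config.learning_rate
    if policy == "decay":
        steps = len(epoch_history) // config.decay_interval
        return config.decay_initial * config.decay_factor**steps
    if policy == "plateau":
        lr = config.learning_rate
        best = math.inf
        stagnant = 0
        for rec in epoch_history:
            vl = rec["val_loss"]
            if vl < best - 1e-12:
                best = vl
                stagnant = 0
            else:
                stagnant += 1
                if stagnant >= config.plateau_patience:
                    lr *= config.plateau_factor
                    stagnant = 0
        return lr
    raise ValueError(f"unknown lr policy '{policy}'")


def fit(
    model: CapsNet,
    train_set: SpectrumDataset,
    val_set: SpectrumDataset,
    config: TrainConfig = TrainConfig(),
) -> list[dict]:
    """Train in place; returns the per-epoch history.

    Each history record carries epoch, lr, train/val margin loss and
    accuracy.  Training stops at the epoch limit or when the train/val
    margin-loss gap exceeds `early_stop_gap` (relative to the training
    loss by default); with `restore_best` the weights of the best
    validation-loss epoch are restored at the end.  Runs are
    reproducible for a fixed seed.
    """
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    # input scaling to [0, 1] fitted on the training set
    lo, hi = train_set.X.min(), train_set.X.max()
    model.input_offset = float(lo)
    model.input_scale = float(hi - lo) if hi > lo else 1.0

    opt = Adam(model.parameters(), lr=(
        config.decay_initial if config.lr_policy == "decay" else config.learning_rate
    ))
    history: list[dict] = []
    best_val = math.inf
    best_weights = None
    ytr = _onehot(train_set.y, model.config.n_classes)

    for epoch in range(config.epochs):
        opt.lr = lr_schedule(config.lr_policy, history, config)
        order = rng.permutation(len(train_set))
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            out = model.forward(train_set.X[idx], labels_onehot=ytr[idx])
            total, _ = model.loss(out, ytr[idx])
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
        tr_loss, tr_acc = _epoch_eval(model, train_set)
        va_loss, va_acc = _epoch_eval(model, val_set)
        rec = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": tr_loss,
            "train_acc": tr_acc,
            "val_loss": va_loss,
            "val_acc": va_acc,
        }
        history.append(rec)
        logger.info(
            "epoch %d lr=%.2e train_loss=%.4f val_loss=%.4f val_acc=%.3f",
            epoch, opt.lr, tr_loss, va_loss, va_acc,
        )
        if va_loss < best_val:
            best_val = va_loss
            if config.restore_best:
                best_weights = model.get_weights()
        if config.early_stop_gap is not None:
            gap = abs(va_loss - tr_loss)
            if config.early_stop_mode == "relative":
                gap = gap / tr_loss if tr_loss > 0 else 0.0
            if gap > config.early_stop_gap:
                logger.info("early stop at epoch %d: loss gap %.3f", epoch, gap)
                break
    if config.restore_best and best_weights is not None:
        model.set_weights(best_weights)
    return history


def _epoch_eval(model: CapsNet, ds: SpectrumDataset) -> tuple[float, float]:
    """(mean margin loss, accuracy by longest capsule) without gradients."""
    from .capsnet import margin_loss

    norms = model.scores(ds.X)
    y1 = _onehot(ds.y, model.config.n_classes)
    ml = margin_loss(norms, y1, model.loss_params)
    acc = float((norms.argmax(axis=1) == ds.y).mean())
    return float(ml.data), acc


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Fractions derived from the confusion counts.

    precision = TP/(TP+FP); recall = TP/(TP+FN);
    abnormal_precision = TN/(TN+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/total; f1 = harmonic mean of precision and
    recall.  A zero denominator yields None (undefined), never 0.
    """
    if cm.total == 0:
        return {k: None for k in
                ("precision", "recall", "f1", "accuracy",
                 "abnormal_precision", "specificity")}

    def ratio(num, den):
        return num / den if den > 0 else None

    precision = ratio(cm.tp, cm.tp + cm.fp)
    recall = ratio(cm.tp, cm.tp + cm.fn)
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision is not None and recall is not None and precision + recall > 0
        else None
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "accuracy": ratio(cm.tp + cm.tn, cm.total),
        "abnormal_precision": ratio(cm.tn, cm.tn + cm.fn),
        "specificity": ratio(cm.tn, cm.tn + cm.fp),
    }


def evaluate(
    model: CapsNet,
    dataset: SpectrumDataset,
    threshold: float | None = None,
    positive_label: int = NORMAL,
) -> EvalReport:
    """Score a labeled set and build the full report.

    The continuous score is the positive-class capsule length; the
    confusion matrix digitizes it at `threshold` (the model's default T
    when omitted), and the ROC sweeps it, with AUC by the trapezoidal
    rule.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    T = model.loss_params.threshold if threshold is None else threshold
    norms = model.scores(dataset.X)
    score = norms[:, positive_label]
    is_pos = dataset.y == positive_label
    pred_pos = score**2 > T**2
    cm = ConfusionMatrix(
        tp=int(np.sum(pred_pos & is_pos)),
        fp=int(np.sum(pred_pos & ~is_pos)),
        fn=int(np.sum(~pred_pos & is_pos)),
        tn=int(np.sum(~pred_pos & ~is_pos)),
    )
    if is_pos.all() or (~is_pos).all():
        roc_pts, auc_val = [], None
    else:
        fpr, tpr, _ = _roc_curve(is_pos.astype(int), score)
        roc_pts = list(zip(fpr.tolist(), tpr.tolist()))
        auc_val = float(_trapezoid_auc(fpr, tpr))
    return EvalReport(
        confusion=cm,
        metrics=metrics_from_confusion(cm),
        roc=roc_pts,
        auc=auc_val,
    )


def aggregate_by_recording(
    dataset: SpectrumDataset, norms: np.ndarray, positive_label: int = NORMAL
) -> dict[str, int]:
    """Optional recording-level decision: majority vote over a
    recording's segments (ties break to abnormal)."""
    votes: dict[str, list[int]] = {}
    pred = norms.argmax(axis=1)
    for sid, p in zip(dataset.ids, pred):
        votes.setdefault(sid.split("#")[0], []).append(int(p))
    out = {}
    for rid, vs in votes.items():
        n_pos = sum(v == positive_label for v in vs)
        out[rid] = positive_label if n_pos * 2 > len(vs) else 1 - positive_label
    return out


def write_report(report: EvalReport, out_dir) -> None:
    """JSON report plus CSV confusion matrix and ROC points."""
    from pathlib import Path
    import csv as _csv

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    with open(out_dir / "confusion.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["", "pred_normal", "pred_abnormal"])
        c = report.confusion
        w.writerow(["true_normal", c.tp, c.fn])
        w.writerow(["true_abnormal", c.fp, c.tn])
    with open(out_dir / "roc.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["fpr", "tpr"])
        for f, t in report.roc:
            w.writerow([f, t])
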