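"""Training engine and the full evaluation-statistics suite.

Training follows the recipe: stochastic gradient descent with momentum 0.9,
30 epochs, batch size 128, learning rate 0.01, L2 penalty 1e-4, an 80:20
stratified train/validation split, every-epoch shuffling, and checkpoint
selection by best validation accuracy.

Evaluation covers everything reported from a confusion matrix: per-class and
macro precision/recall/F1, overall accuracy, sensitivity/specificity for a
designated support class, geometric mean, balanced accuracy, Wilson and
normal-approximation confidence intervals for accuracy, an exact one-sided
binomial test against a baseline proportion, and one-vs-rest
precision-recall curves from model probabilities.

All rates in :class:`MetricsReport` are on the percent scale at full
precision; :meth:`MetricsReport.rounded` applies half-up two-decimal display
rounding.
"""

from __future__ import annotations

import copy
import csv
import json
import warnings
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
from scipy.stats import binom
from statsmodels.stats.proportion import proportion_confint

from . import autograd as ag
from .autograd import Tensor
from .data import LabeledImageSet
from .network import Network

__all__ = ["TrainConfig", "TrainResult", "ConfusionMatrix", "MetricsReport",
           "AccuracyInference", "PRCurve", "train", "predict",
           "confusion_matrix", "classification_metrics", "accuracy_inference",
           "pr_curves"]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    """Optimizer and schedule hyperparameters (defaults: the published recipe)."""

    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 1e-4
    split_fraction: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        for name in ("epochs", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate < 0:  # 0 is legal: a zero step leaves weights fixed
            raise ValueError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")


@dataclass
class TrainResult:
    best_state: dict[str, np.ndarray]
    best_epoch: int
    best_val_accuracy: float
    history: list[dict]


def _nchw(images: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(images.transpose(0, 3, 1, 2), dtype=np.float32)


def _epoch_eval(model: Network, dataset: LabeledImageSet,
                batch_size: int) -> tuple[float, float]:
    """(mean cross-entropy, accuracy fraction) in evaluation mode."""
    model.eval()
    losses, correct = [], 0
    for start in range(0, len(dataset), batch_size):
        idx = slice(start, start + batch_size)
        x = Tensor(_nchw(dataset.images[idx]))
        y = dataset.labels[idx]
        logits = model.forward(x)
        losses.append(float(ag.softmax_cross_entropy(logits, y).data) * len(y))
        correct += int((logits.data.argmax(axis=1) == y).sum())
    return sum(losses) / len(dataset), correct / len(dataset)


def train(model: Network, train_set: LabeledImageSet, val_set: LabeledImageSet,
          cfg: TrainConfig, log=None) -> TrainResult:
    """SGD-with-momentum training; returns the best-validation checkpoint.

    The velocity update is ``v = momentum*v + (grad + weight_decay*w)``;
    ``w -= learning_rate * v``.  Batches are reshuffled every epoch from the
    config seed; the last partial batch is used.  Deterministic given the
    seed.  Raises ``RuntimeError`` on a non-finite loss.
    """
    cfg.validate()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train/val sets must be non-empty")
    if list(train_set.class_names) != list(val_set.class_names):
        raise ValueError("train and validation class names differ")
    if model.cfg.num_classes != len(train_set.class_names):
        raise ValueError(
            f"model has {model.cfg.num_classes} classes, dataset has "
            f"{len(train_set.class_names)}")
    rng = np.random.default_rng(cfg.seed)
    params = dict(model.named_parameters())
    velocity = {name: np.zeros_like(p.data) for name, p in params.items()}
    best = TrainResult(best_state=copy.deepcopy(model.state_dict()),
                       best_epoch=0, best_val_accuracy=-1.0, history=[])
    for epoch in range(1, cfg.epochs + 1):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss, correct = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = Tensor(_nchw(train_set.images[idx]))
            y = train_set.labels[idx]
            for p in params.values():
                p.zero_grad()
            logits = model.forward(x)
            loss = ag.softmax_cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            loss.backward()
            for name, p in params.items():
                g = p.grad + cfg.weight_decay * p.data
                velocity[name] = cfg.momentum * velocity[name] + g
                p.data = p.data - cfg.learning_rate * velocity[name]
            epoch_loss += float(loss.data) * len(y)
            correct += int((logits.data.argmax(axis=1) == y).sum())
        val_loss, val_acc = _epoch_eval(model, val_set, cfg.batch_size)
        record = {"epoch": epoch,
                  "train_loss": epoch_loss / len(train_set),
                  "train_accuracy": correct / len(train_set),
                  "val_loss": val_loss,
                  "val_accuracy": val_acc}
        best.history.append(record)
        if log is not None:
            log(record)
        if val_acc > best.best_val_accuracy:
            best.best_val_accuracy = val_acc
            best.best_epoch = epoch
            best.best_state = copy.deepcopy(model.state_dict())
    model.load_state_dict(best.best_state)
    return best


def predict(model: Network, dataset: LabeledImageSet,
            batch_size: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """(probability matrix, argmax labels); ties break to the lower index."""
    if model.cfg.num_classes != len(dataset.class_names):
        raise ValueError(
            f"model has {model.cfg.num_classes} classes, dataset has "
            f"{len(dataset.class_names)}")
    probs = model.predict_proba(dataset.images, batch_size=batch_size)
    return probs, probs.argmax(axis=1)


# ---------------------------------------------------------------------------
# confusion matrix and derived metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """k x k integer counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = self.counts.shape[0]
        if self.counts.ndim != 2 or self.counts.shape[1] != k:
            raise ValueError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix counts must be non-negative")
        if not self.class_names:
            self.class_names = [f"class{i}" for i in range(k)]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_binary_counts(cls, tp: int, fn: int, fp: int, tn: int,
                           class_names=("positive", "negative"),
                           ) -> "ConfusionMatrix":
        """Binary matrix with the support (positive) class at index 0."""
        return cls(np.array([[tp, fn], [fp, tn]]), list(class_names))


def confusion_matrix(y_true, y_pred, k: int,
                     class_names: list[str] | None = None) -> ConfusionMatrix:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for name, v in (("true", y_true), ("predicted", y_pred)):
        if v.size and (v.min() < 0 or v.max() >= k):
            raise ValueError(f"{name} labels outside [0, {k})")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names or [])


@dataclass
class MetricsReport:
    """Percent-scale classification statistics (full precision)."""

    class_names: list[str]
    per_class_precision: list[float]
    per_class_recall: list[float]
    per_class_f1: list[float]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    accuracy: float
    balanced_accuracy: float
    support_class: int
    sensitivity: float | None
    specificity: float | None
    g_mean: float | None
    accuracy_ci_wilson: tuple[float, float]
    accuracy_ci_normal: tuple[float, float]
    baseline: float
    p_value_vs_baseline: float

    def rounded(self, decimals: int = 2) -> dict:
        """Display dict with half-up rounding, as printed in reports."""
        q = Decimal(10) ** -decimals

        def r(x):
            if x is None:
                return None
            if isinstance(x, (list, tuple)):
                return [r(v) for v in x]
            return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))

        d = asdict(self)
        return {k: (v if k in ("class_names", "support_class", "baseline",
                               "p_value_vs_baseline") else r(v))
                for k, v in d.items()}


def _safe_rate(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", RuntimeWarning,
                      stacklevel=3)
        return 0.0
    return num / den


def classification_metrics(cm: ConfusionMatrix, support_class: int = 0,
                           baseline: float = 0.85) -> MetricsReport:
    """All reported statistics from a confusion matrix.

    ``support_class`` designates the clinically positive class (sensitivity =
    its recall); specificity and G-mean are defined for the binary case.
    The exact binomial test compares overall accuracy against ``baseline``.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(np.float64)
    k = c.shape[0]
    if not 0 <= support_class < k:
        raise ValueError(f"support_class {support_class} outside [0, {k})")
    tp = np.diag(c)
    precision = np.array([_safe_rate(tp[i], c[:, i].sum(), f"precision[{i}]")
                          for i in range(k)])
    recall = np.array([_safe_rate(tp[i], c[i].sum(), f"recall[{i}]")
                       for i in range(k)])
    f1 = np.array([_safe_rate(2 * precision[i] * recall[i],
                              precision[i] + recall[i], f"F1[{i}]")
                   for i in range(k)])
    accuracy = tp.sum() / cm.total
    balanced = recall.mean()
    sens = spec = gmean = None
    if k == 2:
        sens = recall[support_class]
        spec = recall[1 - support_class]
        gmean = float(np.sqrt(sens * spec))
    inference = accuracy_inference(int(tp.sum()), cm.total, baseline)
    pct = 100.0
    return MetricsReport(
        class_names=list(cm.class_names),
        per_class_precision=list(precision * pct),
        per_class_recall=list(recall * pct),
        per_class_f1=list(f1 * pct),
        macro_precision=float(precision.mean() * pct),
        macro_recall=float(recall.mean() * pct),
        macro_f1=float(f1.mean() * pct),
        accuracy=float(accuracy * pct),
        balanced_accuracy=float(balanced * pct),
        support_class=support_class,
        sensitivity=None if sens is None else float(sens * pct),
        specificity=None if spec is None else float(spec * pct),
        g_mean=None if gmean is None else float(gmean * pct),
        accuracy_ci_wilson=tuple(v * pct for v in inference.ci_wilson),
        accuracy_ci_normal=tuple(v * pct for v in inference.ci_normal),
        baseline=baseline,
        p_value_vs_baseline=inference.p_value,
    )


@dataclass
class AccuracyInference:
    """Proportion-scale CI bounds and exact one-sided binomial p-value."""

    ci_wilson: tuple[float, float]
    ci_normal: tuple[float, float]
    p_value: float


def accuracy_inference(correct: int, n: int, baseline: float) -> AccuracyInference:
    """95% accuracy CIs (Wilson primary, normal secondary) and the exact
    one-sided binomial tail P(X >= correct | n, baseline)."""
    if not 0 <= correct <= n:
        raise ValueError(f"correct={correct} outside [0, {n}]")
    if not 0 < baseline < 1:
        raise ValueError("baseline must be in (0, 1)")
    wilson = proportion_confint(correct, n, alpha=0.05, method="wilson")
    normal = proportion_confint(correct, n, alpha=0.05, method="normal")
    p_value = float(binom.sf(correct - 1, n, baseline))
    return AccuracyInference(ci_wilson=(float(wilson[0]), float(wilson[1])),
                             ci_normal=(float(normal[0]), float(normal[1])),
                             p_value=p_value)


# ---------------------------------------------------------------------------
# precision-recall curves
# ---------------------------------------------------------------------------

@dataclass
class PRCurve:
    class_index: int
    thresholds: np.ndarray   # descending distinct scores
    precision: np.ndarray
    recall: np.ndarray


def pr_curves(probs: np.ndarray, y_true) -> list[PRCurve]:
    """One-vs-rest PR curves over all distinct probability thresholds.

    A sample is predicted positive at threshold t when its score >= t, so
    recall is non-increasing as the threshold rises.  The sweep stops at the
    first threshold reaching full recall: beyond it recall is constant and
    precision only decays, so those points carry no information.
    """
    probs = np.asarray(probs, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    if probs.ndim != 2 or probs.shape[0] != y_true.shape[0]:
        raise ValueError("probability matrix does not match labels")
    if np.unique(y_true).size < 2:
        raise ValueError("PR curves need at least two classes in the truth vector")
    curves = []
    for c in range(probs.shape[1]):
        scores = probs[:, c]
        pos = (y_true == c).astype(np.int64)
        n_pos = int(pos.sum())
        order = np.argsort(-scores, kind="stable")
        s_sorted = scores[order]
        tp = np.cumsum(pos[order])
        fp = np.cumsum(1 - pos[order])
        # last occurrence of each distinct score = totals at that threshold
        last = np.flatnonzero(np.diff(s_sorted) != 0)
        last = np.concatenate([last, [len(s_sorted) - 1]])
        thresholds = s_sorted[last]
        tp_t, fp_t = tp[last].astype(float), fp[last].astype(float)
        if n_pos:
            stop = int(np.searchsorted(tp_t, n_pos)) + 1  # first full-recall point
            thresholds, tp_t, fp_t = thresholds[:stop], tp_t[:stop], fp_t[:stop]
        precision = np.where(tp_t + fp_t > 0, tp_t / np.maximum(tp_t + fp_t, 1), 0.0)
        recall = tp_t / n_pos if n_pos else np.zeros_like(tp_t)
        curves.append(PRCurve(c, thresholds, precision, recall))
    return curves


# ---------------------------------------------------------------------------
# report writers
# ---------------------------------------------------------------------------

def write_metrics(report: MetricsReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(json.dumps(report.rounded(), indent=2))
    with open(out / "metrics.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["metric", "class", "value_percent"])
        r = report.rounded()
        for i, name in enumerate(report.class_names):
            writer.writerow(["precision", name, r["per_class_precision"][i]])
            writer.writerow(["recall", name, r["per_class_recall"][i]])
            writer.writerow(["f1", name, r["per_class_f1"][i]])
        for key in ("macro_precision", "macro_recall", "macro_f1", "accuracy",
                    "balanced_accuracy", "sensitivity", "specificity", "g_mean"):
            writer.writerow([key, "overall", r[key]])


def write_confusion(cm: ConfusionMatrix, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred"] + list(cm.class_names))
        for name, row in zip(cm.class_names, cm.counts):
            writer.writerow([name] + [int(v) for v in row])


def write_history(history: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0]))
        writer.writeheader()
        writer.writerows(history)


def write_pr_curves(curves: list[PRCurve], class_names: list[str], out_dir,
                    plot: bool = True) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "pr_curves.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "threshold", "precision", "recall"])
        for curve in curves:
            for t, p, r in zip(curve.thresholds, curve.precision, curve.recall):
                writer.writerow([class_names[curve.class_index], t, p, r])
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for curve in curves:
            ax.plot(curve.recall, curve.precision, marker=".",
                    label=class_names[curve.class_index])
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
        ax.set_xlim(0, 1.02)
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "pr_curves.png", dpi=120)
        plt.close(fig)
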