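"""Dice objective and confusion-matrix evaluation for vessel/background pixels.

The training loss is 1 - soft Dice, where the soft Dice of a probability map
p against a binary truth g is (2*sum(p*g) + w) / (sum(p) + sum(g) + w) with a
small smoothing constant w guarding the empty-empty case.  Evaluation uses
the five confusion-matrix ratios (Dice, accuracy, sensitivity, specificity,
precision) plus areas under the ROC and precision-recall curves obtained by
trapezoidal integration over all distinct score thresholds.  Metrics are
computed inside the field-of-view mask by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

from .nn.tensor import Tensor

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "dice_coefficient",
    "soft_dice",
    "dice_loss",
    "dice_loss_tensor",
    "confusion",
    "report",
    "metrics_from_counts",
    "aggregate_reports",
]

DEFAULT_SMOOTHING = 1e-5


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """Per-image (or aggregate) scores; undefined ratios are NaN."""

    dice: float
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    auc_roc: float
    auc_pr: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def to_record(self) -> str:
        return "\n".join(f"{k}\t{v:.6f}" for k, v in self.to_dict().items())


def _check_same_shape(a, b):
    if np.shape(a) != np.shape(b):
        raise ValueError(f"shape mismatch: {np.shape(a)} vs {np.shape(b)}")


def dice_coefficient(pred: np.ndarray, truth: np.ndarray, w: float = 0.0) -> float:
    """Hard Dice overlap (2|P∩G| + w) / (|P| + |G| + w) of two binary masks."""
    _check_same_shape(pred, truth)
    p = np.asarray(pred).astype(bool)
    g = np.asarray(truth).astype(bool)
    num = 2.0 * np.logical_and(p, g).sum() + w
    den = p.sum() + g.sum() + w
    if den == 0:
        raise ZeroDivisionError("both masks empty and w == 0")
    return float(num / den)


def soft_dice(probs: np.ndarray, truth: np.ndarray, w: float = DEFAULT_SMOOTHING) -> float:
    """Differentiable Dice with soft intersection sum(p*g) and totals."""
    _check_same_shape(probs, truth)
    p = np.asarray(probs, dtype=np.float64)
    g = np.asarray(truth, dtype=np.float64)
    return float((2.0 * (p * g).sum() + w) / (p.sum() + g.sum() + w))


def dice_loss(probs: np.ndarray, truth: np.ndarray, w: float = DEFAULT_SMOOTHING) -> float:
    """Training objective 1 - soft Dice (exactly complementary by construction)."""
    return 1.0 - soft_dice(probs, truth, w)


def dice_loss_tensor(probs: Tensor, truth: Tensor, w: float = DEFAULT_SMOOTHING) -> Tensor:
    """Autodiff version of :func:`dice_loss` used by the training loop."""
    inter = (probs * truth).sum()
    total = probs.sum() + truth.sum()
    return 1.0 - (2.0 * inter + w) / (total + w)


def confusion(
    pred: np.ndarray, truth: np.ndarray, fov: np.ndarray | None = None
) -> ConfusionCounts:
    """Four-way pixel classification, restricted to fov==1 when given."""
    _check_same_shape(pred, truth)
    p = np.asarray(pred).astype(bool).ravel()
    g = np.asarray(truth).astype(bool).ravel()
    if fov is not None:
        _check_same_shape(pred, fov)
        keep = np.asarray(fov).astype(bool).ravel()
        p, g = p[keep], g[keep]
    return ConfusionCounts(
        tp=int(np.sum(p & g)),
        tn=int(np.sum(~p & ~g)),
        fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN", stacklevel=3)
        return float("nan")
    return float(num / den)


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    return {
        "dice": _ratio(2 * c.tp, 2 * c.tp + c.fn + c.fp, "dice"),
        "accuracy": _ratio(c.tp + c.tn, c.total, "accuracy"),
        "sensitivity": _ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": _ratio(c.tn, c.tn + c.fp, "specificity"),
        "precision": _ratio(c.tp, c.tp + c.fp, "precision"),
    }


def roc_points(scores, truth):
    fpr, tpr, _ = roc_curve(truth, scores)
    return fpr, tpr


def pr_points(scores, truth):
    precision, recall, _ = precision_recall_curve(truth, scores)
    return recall[::-1], precision[::-1]


def auc_roc(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the ROC curve by trapezoidal integration."""
    fpr, tpr = roc_points(np.ravel(scores), np.ravel(truth))
    return float(np.trapezoid(tpr, fpr))


def auc_pr(scores: np.ndarray, truth: np.ndarray) -> float:
    """Area under the precision-recall curve by trapezoidal integration."""
    recall, precision = pr_points(np.ravel(scores), np.ravel(truth))
    return float(np.trapezoid(precision, recall))


def report(
    scores: np.ndarray,
    truth: np.ndarray,
    fov: np.ndarray | None = None,
    threshold: float = 0.5,
) -> MetricReport:
    """Score one image: threshold, count, and derive all seven metrics."""
    _check_same_shape(scores, truth)
    s = np.asarray(scores, dtype=np.float64).ravel()
    g = np.asarray(truth).astype(bool).ravel()
    if fov is not None:
        keep = np.asarray(fov).astype(bool).ravel()
        s, g = s[keep], g[keep]
    pred = s >= threshold
    counts = ConfusionCounts(
        tp=int(np.sum(pred & g)),
        tn=int(np.sum(~pred & ~g)),
        fp=int(np.sum(pred & ~g)),
        fn=int(np.sum(~pred & g)),
    )
    ratios = metrics_from_counts(counts)
    if g.any() and not g.all():
        a_roc, a_pr = auc_roc(s, g), auc_pr(s, g)
    else:
        warnings.warn("single-class truth: AUCs undefined, reported as NaN", stacklevel=2)
        a_roc = a_pr = float("nan")
    return MetricReport(auc_roc=a_roc, auc_pr=a_pr, **ratios)


def aggregate_reports(reports: list[MetricReport]) -> MetricReport:
    """Arithmetic mean of per-image metrics (NaNs ignored per field)."""
    vals = {
        f.name: np.nanmean([getattr(r, f.name) for r in reports]) for f in fields(MetricReport)
    }
    return MetricReport(**{k: float(v) for k, v in vals.items()})
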