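"""Evaluation metrics: confusion matrix, per-class precision/recall/F1,
macro/weighted/micro aggregates, one-vs-rest ROC/AUC, top-1 error,
cross-validation aggregation, and an accuracy-vs-complexity score.

AUC is computed with the rank statistic (Mann–Whitney; ties credited
half), per class one-vs-rest; the macro average is the unweighted mean
over classes and the micro variant pools the (score, indicator) pairs
of all classes before ranking.  Argmax predictions break ties toward
the lowest class index so reports are deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, InputError
from .model import BoneCNN


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints; rows = true class, cols = predicted
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ConfigurationError(f"confusion matrix must be square, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ConfigurationError("confusion matrix entries must be non-negative")
        if not self.class_names:
            self.class_names = [f"class_{i}" for i in range(self.counts.shape[0])]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.counts, index=self.class_names, columns=self.class_names).to_csv(path)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def validate(self) -> None:
        if (np.diff(self.fpr) < 0).any() or (np.diff(self.tpr) < 0).any():
            raise ConfigurationError("ROC points must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0 and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise ConfigurationError("ROC must run from (0,0) to (1,1)")
        if not 0.0 <= self.auc <= 1.0:
            raise ConfigurationError("AUC must lie in [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr}).to_csv(path, index=False)


@dataclass
class EvalReport:
    accuracy: float
    top1_error: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    auc: np.ndarray  # per class, NaN when undefined
    macro_f1: float
    weighted_f1: float
    macro_auc: float
    micro_auc: float
    confusion: ConfusionMatrix
    roc_curves: dict[int, RocCurve] = field(default_factory=dict)

    def to_dict(self) -> dict:
        per_class = []
        for i, name in enumerate(self.confusion.class_names):
            per_class.append(
                {
                    "class": name,
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "support": int(self.support[i]),
                    "auc": None if np.isnan(self.auc[i]) else float(self.auc[i]),
                }
            )
        return {
            "accuracy": self.accuracy,
            "top1_error": self.top1_error,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "macro_auc": self.macro_auc,
            "micro_auc": self.micro_auc,
            "per_class": per_class,
            "confusion": self.confusion.counts.tolist(),
            "class_names": self.confusion.class_names,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# Core metric operations
# ---------------------------------------------------------------------------


def confusion(y_true, y_pred, num_classes: int, class_names: list[str] | None = None) -> ConfusionMatrix:
    """K x K count matrix; entry (i, j) counts true i predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise InputError(f"label vectors must be 1-D and equal length, got {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise InputError("cannot build a confusion matrix from empty inputs")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise InputError(f"{name} labels outside 0..{num_classes - 1}")
    counts = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts, class_names or [])


def per_class_prf(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precision, recall, F1 and support per class.

    Zero denominators (a class never predicted, or with no true
    instances) yield 0 with a warning."""
    counts = cm.counts.astype(np.float64)
    tp = np.diag(counts)
    pred_totals = counts.sum(axis=0)
    true_totals = counts.sum(axis=1)
    if (pred_totals == 0).any() or (true_totals == 0).any():
        warnings.warn("zero denominator in precision/recall; reporting 0 for affected classes")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_totals > 0, tp / pred_totals, 0.0)
        recall = np.where(true_totals > 0, tp / true_totals, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return precision, recall, f1, true_totals.astype(np.int64)


def aggregate(f1: np.ndarray, support: np.ndarray, cm: ConfusionMatrix | None = None) -> dict:
    """Macro (unweighted) and weighted (support-weighted) F1; with a
    confusion matrix also accuracy and top-1 error."""
    f1 = np.asarray(f1, dtype=np.float64)
    support = np.asarray(support, dtype=np.float64)
    out = {
        "macro_f1": float(f1.mean()),
        "weighted_f1": float((f1 * support).sum() / support.sum()),
    }
    if cm is not None:
        out["accuracy"] = cm.accuracy
        out["top1_error"] = 1.0 - cm.accuracy
    return out


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    pos = labels.astype(bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)  # average ranks -> half credit for ties
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC polygon over descending score thresholds (ties grouped)."""
    order = np.argsort(-scores, kind="stable")
    s, l = scores[order], labels[order].astype(bool)
    # group equal scores
    boundaries = np.nonzero(np.diff(s))[0]
    tp = np.cumsum(l)[np.append(boundaries, len(s) - 1)]
    fp = np.cumsum(~l)[np.append(boundaries, len(s) - 1)]
    tpr = np.concatenate([[0.0], tp / max(l.sum(), 1)])
    fpr = np.concatenate([[0.0], fp / max((~l).sum(), 1)])
    return fpr, tpr


def roc_auc(
    scores: np.ndarray, y_true: np.ndarray
) -> tuple[dict[int, RocCurve], float, float, np.ndarray]:
    """One-vs-rest ROC/AUC per class, plus macro and micro averages.

    ``scores`` is (n, K); class c's curve uses column c against the
    indicator ``y == c``.  Classes with no positives or no negatives are
    excluded from the macro average with a warning.  The micro AUC pools
    all (score, indicator) pairs across classes before ranking.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise InputError(f"scores {scores.shape} incompatible with labels {y_true.shape}")
    k = scores.shape[1]
    curves: dict[int, RocCurve] = {}
    aucs = np.full(k, np.nan)
    onehot = np.zeros_like(scores)
    onehot[np.arange(len(y_true)), y_true] = 1.0
    for c in range(k):
        labels = onehot[:, c]
        if labels.sum() == 0 or labels.sum() == len(labels):
            warnings.warn(f"class {c}: AUC undefined (no positives or no negatives); excluded from macro")
            continue
        auc = _rank_auc(scores[:, c], labels)
        fpr, tpr = _roc_points(scores[:, c], labels)
        curve = RocCurve(fpr=fpr, tpr=tpr, auc=auc)
        curve.validate()
        curves[c] = curve
        aucs[c] = auc
    macro = float(np.nanmean(aucs)) if not np.isnan(aucs).all() else float("nan")
    micro = _rank_auc(scores.ravel(), onehot.ravel())
    return curves, macro, micro, aucs


def cv_aggregate(fold_rows: list[dict] | pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Mean and sample standard deviation per metric across folds."""
    df = pd.DataFrame(fold_rows)
    if len(df) < 2:
        raise InputError("cross-validation aggregation needs at least two folds")
    out = {}
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            out[col] = (float(df[col].mean()), float(df[col].std(ddof=1)))
    return out


def normalized_score(
    accuracy: float,
    parameters: float,
    reference_accuracy: float,
    reference_parameters: float,
    weight: float = 0.5,
) -> float:
    """Accuracy-vs-complexity composite, clipped to [0, 1].

    ``weight * (acc / acc_ref) + (1 - weight) * (params_ref / params)``.
    The combination rule is a package convention (recorded wherever the
    score is reported); a model identical to the reference scores 1.
    """
    if parameters <= 0 or reference_parameters <= 0:
        raise InputError("parameter counts must be positive")
    if not 0.0 <= weight <= 1.0:
        raise InputError(f"weight must lie in [0, 1], got {weight}")
    score = weight * (accuracy / reference_accuracy) + (1 - weight) * (
        reference_parameters / parameters
    )
    return float(np.clip(score, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Whole-model evaluation
# ---------------------------------------------------------------------------


def evaluate_model(
    model: BoneCNN,
    x: np.ndarray,
    y: np.ndarray,
    class_names: list[str] | None = None,
    batch_size: int = 32,
) -> EvalReport:
    """Single evaluation pass: probabilities, argmax predictions (ties
    to the lowest index), and the full metric report."""
    y = np.asarray(y, dtype=np.int64)
    probs = np.concatenate(
        [model.predict_proba(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    )
    preds = probs.argmax(axis=1)
    k = model.config.num_classes
    cm = confusion(y, preds, k, class_names)
    precision, recall, f1, support = per_class_prf(cm)
    agg = aggregate(f1, support, cm)
    curves, macro_auc, micro_auc, aucs = roc_auc(probs, y)
    report = EvalReport(
        accuracy=agg["accuracy"],
        top1_error=agg["top1_error"],
        precision=precision,
        recall=recall,
        f1=f1,
        support=support,
        auc=aucs,
        macro_f1=agg["macro_f1"],
        weighted_f1=agg["weighted_f1"],
        macro_auc=macro_auc,
        micro_auc=micro_auc,
        confusion=cm,
        roc_curves=curves,
    )
    return report
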