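"""Test-set evaluation: K-way confusion matrix, per-class one-vs-rest
matrices, macro-averaged metrics, ROC and precision-recall curves.

Macro (unweighted) averaging over classes is the reporting convention: it is
the convention that reproduces the published metric table from the published
misclassification counts exactly.  A class with no predicted (or no actual)
members contributes 0 to the affected metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm

from .data import ArrayDataset
from .graph import ArchitectureGraph
from .nn import Params, evaluate_batch


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """counts[i, j] = number of samples with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= num_classes):
            raise ValueError(f"{name} contains labels outside 0..{num_classes - 1}")
    return skm.confusion_matrix(y_true, y_pred, labels=np.arange(num_classes))


def one_vs_rest(cm: np.ndarray) -> list[np.ndarray]:
    """Per-class binary matrices [[TP, FN], [FP, TN]]; each sums to the total."""
    cm = np.asarray(cm)
    total = cm.sum()
    out = []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        out.append(np.array([[tp, fn], [fp, tn]]))
    return out


def classification_metrics(cm: np.ndarray) -> tuple[float, float, float, float]:
    """(accuracy, macro precision, macro recall, macro F1) from a confusion matrix."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = np.trace(cm) / total
    precisions, recalls, f1s = [], [], []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        pred_k = cm[:, k].sum()
        true_k = cm[k].sum()
        p = tp / pred_k if pred_k else 0.0
        r = tp / true_k if true_k else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(f1)
    return (
        float(accuracy),
        float(np.mean(precisions)),
        float(np.mean(recalls)),
        float(np.mean(f1s)),
    )


def roc_pr_curves(y_true_binary, scores):
    """One-vs-rest threshold sweep for a single class.

    Returns (roc_points, roc_auc, pr_points, pr_auc): ROC-AUC by the
    trapezoidal rule, PR-AUC by step-wise interpolation.
    """
    y = np.asarray(y_true_binary, dtype=int)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present; AUC is undefined otherwise")
    fpr, tpr, _ = skm.roc_curve(y, s)
    roc_auc = float(skm.auc(fpr, tpr))
    precision, recall, _ = skm.precision_recall_curve(y, s)
    pr_auc = float(skm.average_precision_score(y, s))  # step-wise sum
    return (
        np.column_stack([fpr, tpr]),
        roc_auc,
        np.column_stack([recall, precision]),
        pr_auc,
    )


@dataclass
class EvalReport:
    confusion: np.ndarray
    per_class_ovr: list[np.ndarray]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    loss: float
    roc_auc: list[float]
    pr_auc: list[float]
    class_names: list[str]

    def to_text(self) -> str:
        lines = ["Confusion matrix (rows = true, cols = predicted):"]
        width = max(len(n) for n in self.class_names)
        header = " " * (width + 2) + "  ".join(f"{n:>{width}}" for n in self.class_names)
        lines.append(header)
        for name, row in zip(self.class_names, self.confusion):
            lines.append(f"{name:>{width}}  " + "  ".join(f"{v:>{width}d}" for v in row))
        lines.append("")
        lines.append(f"Accuracy         {self.accuracy:.4f}")
        lines.append(f"Macro precision  {self.macro_precision:.4f}")
        lines.append(f"Macro recall     {self.macro_recall:.4f}")
        lines.append(f"Macro F1         {self.macro_f1:.4f}")
        lines.append(f"Loss             {self.loss:.4f}")
        for i, name in enumerate(self.class_names):
            lines.append(f"ROC-AUC[{name}]  {self.roc_auc[i]:.4f}   PR-AUC[{name}]  {self.pr_auc[i]:.4f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["metric", "value"])
            w.writerow(["accuracy", self.accuracy])
            w.writerow(["macro_precision", self.macro_precision])
            w.writerow(["macro_recall", self.macro_recall])
            w.writerow(["macro_f1", self.macro_f1])
            w.writerow(["loss", self.loss])
            for i, name in enumerate(self.class_names):
                w.writerow([f"roc_auc_{name}", self.roc_auc[i]])
                w.writerow([f"pr_auc_{name}", self.pr_auc[i]])


def evaluate_model(
    graph: ArchitectureGraph,
    params: Params,
    data: ArrayDataset,
    test_ids: list[int],
    class_names: list[str] | None = None,
) -> EvalReport:
    """Full evaluation of a trained model on a held-out id set."""
    if not test_ids:
        raise ValueError("empty test set")
    X, y = data.X[test_ids], data.y[test_ids]
    loss, _, probs = evaluate_batch(graph, params, X, y)
    y_pred = probs.argmax(axis=1)
    k = graph.num_classes
    cm = confusion_matrix(y, y_pred, k)
    acc, mp, mr, mf1 = classification_metrics(cm)
    roc_aucs, pr_aucs = [], []
    for c in range(k):
        yb = (y == c).astype(int)
        if len(np.unique(yb)) < 2:
            roc_aucs.append(float("nan"))
            pr_aucs.append(float("nan"))
            continue
        _, roc_auc, _, pr_auc = roc_pr_curves(yb, probs[:, c])
        roc_aucs.append(roc_auc)
        pr_aucs.append(pr_auc)
    return EvalReport(
        confusion=cm,
        per_class_ovr=one_vs_rest(cm),
        accuracy=acc,
        macro_precision=mp,
        macro_recall=mr,
        macro_f1=mf1,
        loss=loss,
        roc_auc=roc_aucs,
        pr_auc=pr_aucs,
        class_names=class_names or [f"class{i}" for i in range(k)],
    )
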