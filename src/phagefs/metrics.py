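"""Binary-classification evaluation: sensitivity, specificity, accuracy, ROC.

SN = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/(TP+TN+FP+FN).  A ratio
whose denominator is zero (e.g. SP on an all-positive test set) is reported
as NaN rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import auc, confusion_matrix, roc_curve


@dataclass
class EvalReport:
    tp: int
    fp: int
    tn: int
    fn: int
    sn: float  # NaN when no positives in `actual`
    sp: float  # NaN when no negatives in `actual`
    acc: float
    roc_points: np.ndarray | None = None  # (n, 2): FPR, TPR
    roc_auc: float | None = None
    extras: dict = field(default_factory=dict)

    def summary(self) -> str:
        def fmt(x: float) -> str:
            return "undefined" if np.isnan(x) else f"{100 * x:.2f}%"

        lines = [
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn}",
            f"SN  = {fmt(self.sn)}",
            f"SP  = {fmt(self.sp)}",
            f"ACC = {fmt(self.acc)}",
        ]
        if self.roc_auc is not None:
            lines.append(f"AUC = {self.roc_auc:.4f}")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("metric\tvalue\n")
            for k in ("tp", "fp", "tn", "fn", "sn", "sp", "acc"):
                fh.write(f"{k}\t{getattr(self, k)}\n")
            if self.roc_auc is not None:
                fh.write(f"auc\t{self.roc_auc}\n")

    def write_roc(self, path: str | Path) -> None:
        if self.roc_points is None:
            raise ValueError("no ROC points (no scores were supplied)")
        np.savetxt(
            path,
            self.roc_points,
            delimiter="\t",
            header="fpr\ttpr",
            comments="",
        )


def evaluate(
    predicted: np.ndarray,
    actual: np.ndarray,
    scores: np.ndarray | None = None,
) -> EvalReport:
    """Confusion counts and SN/SP/ACC; ROC when decision scores are given.

    ``predicted`` and ``actual`` are 0/1 label vectors of equal length;
    ``scores`` are real-valued decision scores for the positive class.
    """
    predicted = np.asarray(predicted, dtype=int)
    actual = np.asarray(actual, dtype=int)
    if predicted.shape != actual.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape[0]} predictions vs "
            f"{actual.shape[0]} actual labels"
        )
    if actual.size == 0:
        raise ValueError("empty label vectors")
    tn, fp, fn, tp = confusion_matrix(
        actual, predicted, labels=[0, 1]
    ).ravel()
    sn = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    sp = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    acc = (tp + tn) / actual.size
    roc_points = None
    roc_auc = None
    if scores is not None and len(np.unique(actual)) == 2:
        fpr, tpr, _ = roc_curve(actual, np.asarray(scores, dtype=float))
        roc_points = np.column_stack([fpr, tpr])
        roc_auc = float(auc(fpr, tpr))
    return EvalReport(
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn),
        sn=float(sn), sp=float(sp), acc=float(acc),
        roc_points=roc_points, roc_auc=roc_auc,
    )


def decision_scores(model, X: np.ndarray) -> np.ndarray:
    """Positive-class decision scores from any fitted classifier.

    Uses the native decision function when present, otherwise the
    positive-class probability estimate.
    """
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    return np.asarray(proba[:, classes.index(1)], dtype=float)
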