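"""Confusion-matrix statistics and ranking metrics.

Conventions: the positive class is "link present" at the base level and
"classifier got the link right" (meta-label 1) at the meta level; report
headers restate this so specificity and sensitivity cannot be silently
swapped.  Percentages print to one decimal; raw fractions stay available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = ["ConfusionStats", "confusion", "auroc", "report"]


@dataclass
class ConfusionStats:
    """2x2 confusion counts with derived specificity / sensitivity / accuracy."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")
            setattr(self, name, int(v))
        if self.total == 0:
            raise ValueError("confusion matrix has no observations")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def sp(self) -> float:
        """Specificity, percent: 100 * tn / (tn + fp)."""
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def sn(self) -> float:
        """Sensitivity, percent: 100 * tp / (tp + fn)."""
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def ac(self) -> float:
        """Accuracy, percent: 100 * (tp + tn) / total."""
        return 100.0 * (self.tp + self.tn) / self.total

    def summary(self) -> dict:
        """One-decimal report row (raw counts kept alongside)."""
        return {
            "tp": self.tp,
            "tn": self.tn,
            "fp": self.fp,
            "fn": self.fn,
            "Sp": round(self.sp, 1),
            "Sn": round(self.sn, 1),
            "Ac": round(self.ac, 1),
        }


def confusion(labels: Sequence[int], preds: Sequence[int]) -> ConfusionStats:
    """Count the 2x2 confusion matrix of binary labels vs binary predictions."""
    y = np.asarray(labels)
    p = np.asarray(preds)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
    if y.size == 0:
        raise ValueError("empty input")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary 0/1")
    return ConfusionStats(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


def auroc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve — the probability that a random positive
    outscores a random negative, ties counted half (Mann-Whitney form)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC is undefined when only one class is present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def report(
    model,
    train: pd.DataFrame,
    test: pd.DataFrame,
    features: Sequence[str],
    label: str,
    threshold: float = 0.5,
    positive_meaning: str = "meta-label 1 (topology classifies the pair correctly)",
) -> tuple[pd.DataFrame, str]:
    """Two-series evaluation of a fitted classifier.

    ``model`` needs ``predict_score``; scores are thresholded at
    ``threshold`` unless the model exposes ``predict`` (the linear
    discriminant decides at S >= 0 through its own ``predict``).  Returns a
    tidy frame (one row per series) and a plain-text table.
    """
    rows = []
    for series, table in (("training", train), ("test", test)):
        scores = np.asarray(model.predict_score(table[list(features)]))
        if hasattr(model, "predict"):
            preds = np.asarray(model.predict(table[list(features)]))
        else:
            preds = (scores >= threshold).astype(int)
        stats = confusion(table[label].to_numpy(), preds)
        row = {"series": series, **stats.summary()}
        row["AUROC"] = round(auroc(table[label].to_numpy(), scores), 3)
        rows.append(row)
    frame = pd.DataFrame(rows)
    lines = [
        f"positive class: {positive_meaning}",
        frame.to_string(index=False),
    ]
    return frame, "\n".join(lines)
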