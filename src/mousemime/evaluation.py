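"""Held-out evaluation: confusion matrix and one-vs-rest sensitivity /
specificity per class, reported as percentages.

Sensitivity of a class is its correct positives over all its positives
(diagonal over row sum); specificity is its correct negatives over all
its negatives, with the negatives pooled one-vs-rest from the same
matrix. Undefined ratios (an absent class) are reported as NaN, never 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from mousemime.errors import LabelError
from mousemime.synthetic_faces import STATES


@dataclass
class ConfusionMatrix:
    """counts[i, j] = number of samples of true class i predicted as j."""

    counts: np.ndarray
    classes: tuple[str, ...]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(true_labels, predicted_labels,
              classes=STATES) -> ConfusionMatrix:
    """Tally the (true, predicted) count matrix over the given classes."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise LabelError("label lists must have equal length")
    classes = tuple(classes)
    known = set(classes)
    bad = set(np.unique(np.concatenate([t, p]))) - known
    if bad:
        raise LabelError(f"unknown label(s): {sorted(bad)}")
    counts = _sk_confusion(t, p, labels=list(classes))
    return ConfusionMatrix(counts=counts.astype(int), classes=classes)


def sensitivity_specificity(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Per-class one-vs-rest sensitivity and specificity, in percent.

    sensitivity_i = counts[i, i] / row_i ;
    specificity_i = (total - row_i - col_i + counts[i, i]) / (total - row_i).
    NaN where a class has no positives (or no negatives).
    """
    c = cm.counts.astype(float)
    total = c.sum()
    out: dict[str, dict[str, float]] = {}
    for i, name in enumerate(cm.classes):
        row = c[i].sum()
        col = c[:, i].sum()
        tp = c[i, i]
        tn = total - row - col + tp
        sens = 100.0 * tp / row if row > 0 else float("nan")
        neg = total - row
        spec = 100.0 * tn / neg if neg > 0 else float("nan")
        out[name] = {"sensitivity": sens, "specificity": spec}
    return out
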