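"""Misclassification table and accuracy / false-rate arithmetic.

For five damage classes the evaluation is a 5×5 cross-tabulation — entry
(t, p) counts seeds of true class t predicted as p — from which follow:

* overall classification accuracy  100 · correct / n_total,
* per-class accuracy               100 · counts(c,c) / row-sum(c),
* false-negative percentage        100 · (row-sum(c) − counts(c,c)) / n_total
  (seeds belonging to c that the model put elsewhere),
* false-positive percentage        100 · (col-sum(c) − counts(c,c)) / n_total
  (seeds the model put in c that belong elsewhere),

plus per-variety overall accuracy.  Percentages are carried as exact
rationals internally so conservation identities hold to the digit
(accuracy% + Σ FN% = 100; Σ FN counts = Σ FP counts); floats appear only
at the reporting surface, rounded to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .scoring import ClassificationResult

__all__ = [
    "CLASSES",
    "EvaluationReport",
    "confusion_counts",
    "classification_accuracy",
    "per_class_accuracy",
    "false_negative_pct",
    "false_positive_pct",
    "per_variety_accuracy",
    "evaluate",
]

CLASSES: tuple[int, ...] = (1, 2, 3, 4, 5)


def confusion_counts(results: list[ClassificationResult]) -> np.ndarray:
    """5×5 counts; entry (t−1, p−1) = seeds of true class t predicted p."""
    counts = np.zeros((5, 5), dtype=np.int64)
    for res in results:
        if res.true_class is None:
            raise ValueError(f"seed {res.seed_id} lacks a true class")
        counts[res.true_class - 1, res.predicted_class - 1] += 1
    return counts


def _check(counts: np.ndarray, n_total: int) -> np.ndarray:
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (5, 5):
        raise ValueError("counts must be 5×5")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return counts


def classification_accuracy(counts: np.ndarray, n_total: int) -> Fraction:
    """Overall accuracy (%): 100 × correctly classified / n_total."""
    counts = _check(counts, n_total)
    return Fraction(100 * int(np.trace(counts)), n_total)


def per_class_accuracy(counts: np.ndarray, damage_class: int) -> Fraction:
    """Accuracy (%) within one true class: diagonal over row total."""
    counts = _check(counts, 1)
    row = counts[damage_class - 1]
    total = int(row.sum())
    if total == 0:
        raise ValueError(f"no seeds of class {damage_class}")
    return Fraction(100 * int(row[damage_class - 1]), total)


def false_negative_pct(counts: np.ndarray, damage_class: int, n_total: int) -> Fraction:
    """FN (%): seeds of the class the model sent elsewhere, over n_total."""
    counts = _check(counts, n_total)
    row = counts[damage_class - 1]
    fn = int(row.sum()) - int(row[damage_class - 1])
    return Fraction(100 * fn, n_total)


def false_positive_pct(counts: np.ndarray, damage_class: int, n_total: int) -> Fraction:
    """FP (%): seeds the model put in the class wrongly, over n_total."""
    counts = _check(counts, n_total)
    col = counts[:, damage_class - 1]
    fp = int(col.sum()) - int(col[damage_class - 1])
    return Fraction(100 * fp, n_total)


def per_variety_accuracy(results: list[ClassificationResult]) -> dict[int, Fraction]:
    """Overall accuracy restricted to each variety's seeds."""
    totals: dict[int, int] = {}
    correct: dict[int, int] = {}
    for res in results:
        if res.true_class is None:
            raise ValueError(f"seed {res.seed_id} lacks a true class")
        totals[res.variety_id] = totals.get(res.variety_id, 0) + 1
        if res.predicted_class == res.true_class:
            correct[res.variety_id] = correct.get(res.variety_id, 0) + 1
    return {
        v: Fraction(100 * correct.get(v, 0), n) for v, n in sorted(totals.items())
    }


@dataclass
class EvaluationReport:
    """The full evaluation: counts plus exact per-class and overall rates."""

    counts: np.ndarray
    n_total: int
    overall_accuracy: Fraction
    per_class: dict[int, dict[str, Fraction]]
    per_variety: dict[int, Fraction]

    def to_frame(self) -> pd.DataFrame:
        """Human-readable table: rows = true class, columns = predicted
        class counts, then per-class accuracy, FN% and FP%."""
        rows = []
        for c in CLASSES:
            row = {f"pred_{p}": int(self.counts[c - 1, p - 1]) for p in CLASSES}
            row["accuracy_pct"] = round(float(self.per_class[c]["accuracy"]), 1)
            row["false_negative_pct"] = round(float(self.per_class[c]["fn"]), 1)
            row["false_positive_pct"] = round(float(self.per_class[c]["fp"]), 1)
            rows.append(row)
        frame = pd.DataFrame(rows, index=pd.Index(CLASSES, name="true_class"))
        return frame

    def render(self) -> str:
        lines = [self.to_frame().to_string()]
        lines.append(f"n_total: {self.n_total}")
        lines.append(
            f"overall accuracy: {round(float(self.overall_accuracy), 1)}%"
        )
        if self.per_variety:
            acc = ", ".join(
                f"{v}: {round(float(a), 1)}%" for v, a in self.per_variety.items()
            )
            lines.append(f"per-variety accuracy: {acc}")
        return "\n".join(lines)


def evaluate(results: list[ClassificationResult]) -> EvaluationReport:
    """Cross-tabulate classification results into an EvaluationReport."""
    if not results:
        raise ValueError("no results to evaluate")
    counts = confusion_counts(results)
    n_total = len(results)
    per_class = {}
    for c in CLASSES:
        row_total = int(counts[c - 1].sum())
        per_class[c] = {
            "accuracy": per_class_accuracy(counts, c)
            if row_total
            else Fraction(0),
            "fn": false_negative_pct(counts, c, n_total),
            "fp": false_positive_pct(counts, c, n_total),
        }
    return EvaluationReport(
        counts=counts,
        n_total=n_total,
        overall_accuracy=classification_accuracy(counts, n_total),
        per_class=per_class,
        per_variety=per_variety_accuracy(results),
    )
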