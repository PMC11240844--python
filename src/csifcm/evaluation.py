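"""Segmentation accuracy metrics with ground-truth label matching.

Cluster indices coming out of an unsupervised driver are arbitrary, so
predicted clusters are first matched one-to-one to ground-truth segments by
maximizing total overlap on the contingency table (Hungarian assignment).
Per-segment metrics are then computed one-vs-rest on the matched maps:

* similarity index  rho = 2|S1 ∩ S2| / (|S1| + |S2|)   (the Dice overlap),
* false positive ratio  fpr = (|S2| - |S1 ∩ S2|) / |S1|  (may exceed 1 —
  it is normalized by the ground-truth size, not the prediction size),
* false negative ratio  fnr = (|S1| - |S1 ∩ S2|) / |S1|,
* TPR = TP / |S1| and FPR = FP / N with N the negative count (a
  ``fpr_denominator="positives"`` switch reproduces the alternative FP / P
  reading),

with S1 the ground-truth segment and S2 the prediction.  Overall segmentation
accuracy is the fraction of pixels whose matched predicted label equals the
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


def contingency_table(pred_labels: np.ndarray, true_labels: np.ndarray, c: int) -> np.ndarray:
    """c×c table of pixel counts: entry (i, j) = |pred==i ∩ true==j|."""
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    if pred.size != true.size:
        raise ValueError("label maps must have the same pixel count")
    return np.bincount(pred * c + true, minlength=c * c).reshape(c, c)


def match_clusters(pred_labels: np.ndarray, true_labels: np.ndarray, c: int) -> dict[int, int]:
    """Optimal one-to-one mapping predicted cluster -> ground-truth segment.

    Maximizes the total matched pixel count over the contingency table.
    Label maps with fewer than ``c`` distinct values are handled naturally:
    missing rows/columns are empty and pair up with whatever is left.
    """
    pred = np.asarray(pred_labels).ravel()
    true = np.asarray(true_labels).ravel()
    c = max(c, int(pred.max()) + 1 if pred.size else 1, int(true.max()) + 1 if true.size else 1)
    table = contingency_table(pred, true, c)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return {int(r): int(col) for r, col in zip(rows, cols)}


def apply_mapping(pred_labels: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    """Relabel a predicted map through a cluster -> segment mapping."""
    pred = np.asarray(pred_labels)
    lut = np.arange(max(mapping) + 1)
    for k, v in mapping.items():
        lut[k] = v
    return lut[pred]


def segment_metrics(s1: np.ndarray, s2: np.ndarray) -> tuple[float, float, float]:
    """(rho, fpr, fnr) for one segment from boolean masks S1 (truth), S2 (pred).

    An empty ground-truth segment leaves all three undefined (NaN).
    """
    s1 = np.asarray(s1, dtype=bool).ravel()
    s2 = np.asarray(s2, dtype=bool).ravel()
    if s1.size != s2.size:
        raise ValueError("masks must have the same pixel count")
    n1, n2 = int(s1.sum()), int(s2.sum())
    if n1 == 0:
        return (float("nan"),) * 3
    inter = int((s1 & s2).sum())
    rho = 2.0 * inter / (n1 + n2)
    fpr = (n2 - inter) / n1
    fnr = (n1 - inter) / n1
    return rho, fpr, fnr


def tpr_fpr(
    s1: np.ndarray,
    s2: np.ndarray,
    n_total_pixels: int | None = None,
    fpr_denominator: str = "negatives",
) -> tuple[float, float]:
    """(TPR, FPR) for one segment: TPR = TP/|S1|, FPR = FP/N (or FP/P).

    ``fpr_denominator="negatives"`` (default) uses the standard negative count
    N = total - |S1|; ``"positives"`` divides FP by |S1| instead.  An
    all-positive ground truth leaves FPR undefined under the default.
    """
    s1 = np.asarray(s1, dtype=bool).ravel()
    s2 = np.asarray(s2, dtype=bool).ravel()
    if n_total_pixels is None:
        n_total_pixels = s1.size
    n1 = int(s1.sum())
    if n1 == 0:
        return float("nan"), float("nan")
    tp = int((s1 & s2).sum())
    fp = int((s2 & ~s1).sum())
    tpr = tp / n1
    if fpr_denominator == "positives":
        return tpr, fp / n1
    if fpr_denominator != "negatives":
        raise ValueError("fpr_denominator must be 'negatives' or 'positives'")
    n_neg = n_total_pixels - n1
    return tpr, (fp / n_neg) if n_neg > 0 else float("nan")


def overall_accuracy(
    pred_labels: np.ndarray, true_labels: np.ndarray, mapping: dict[int, int]
) -> float:
    """Fraction of pixels whose mapped predicted label equals the truth."""
    mapped = apply_mapping(pred_labels, mapping)
    true = np.asarray(true_labels)
    return float((mapped.ravel() == true.ravel()).mean())


@dataclass
class EvaluationReport:
    """Per-segment metrics plus the overall segmentation accuracy."""

    per_segment: pd.DataFrame  # columns: segment, rho, fpr, fnr, tpr, fpr_rate
    overall_accuracy: float
    mapping: dict[int, int]

    def to_csv(self, path) -> None:
        """One row per segment plus an overall row, matching the per-segment columns."""
        df = self.per_segment.copy()
        overall = {c: np.nan for c in df.columns}
        overall.update({"segment": "overall", "accuracy": self.overall_accuracy})
        df["accuracy"] = np.nan
        df = pd.concat([df, pd.DataFrame([overall])], ignore_index=True)
        df.to_csv(path, index=False)

    def __str__(self) -> str:
        lines = [self.per_segment.to_string(index=False, float_format=lambda v: f"{v:.4f}")]
        lines.append(f"overall segmentation accuracy: {self.overall_accuracy:.4f}")
        return "\n".join(lines)


def evaluate(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    n_classes: int | None = None,
    fpr_denominator: str = "negatives",
) -> EvaluationReport:
    """Match clusters to ground truth and compute all metrics.

    Segments are the ground-truth classes; each predicted cluster is assigned
    to exactly one via Hungarian matching before the one-vs-rest metrics.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if n_classes is None:
        n_classes = int(max(pred.max(), true.max())) + 1
    mapping = match_clusters(pred, true, n_classes)
    mapped = apply_mapping(pred, mapping)
    rows = []
    for seg in range(n_classes):
        s1 = true == seg
        s2 = mapped == seg
        rho, fpr, fnr = segment_metrics(s1, s2)
        tpr, fpr_rate = tpr_fpr(s1, s2, true.size, fpr_denominator)
        rows.append(
            {"segment": seg, "rho": rho, "fpr": fpr, "fnr": fnr, "tpr": tpr, "fpr_rate": fpr_rate}
        )
    acc = overall_accuracy(pred, true, mapping)
    return EvaluationReport(pd.DataFrame(rows), acc, mapping)
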