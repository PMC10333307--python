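"""Per-lesion AUC evaluation on pooled pixel scores.

Scores for one lesion class are pooled over every annotated pixel of every
image in the split (micro-averaging) and compared with the binary mask.
AUC_ROC is the area under the ROC curve; AUC_PR is computed as average
precision — the sum of precision times recall increments — which avoids the
optimistic bias of trapezoidal interpolation on PR points.  A class with no
positive pixel in the split has no defined AUC and is reported as missing
(``None``), never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (average_precision_score, precision_recall_curve,
                             roc_auc_score, roc_curve)

__all__ = ["AUCResult", "binary_auc"]


@dataclass
class AUCResult:
    class_name: str
    auc_pr: float
    auc_roc: float
    precision: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def to_dict(self) -> dict:
        return {"class": self.class_name,
                "auc_pr": float(self.auc_pr),
                "auc_roc": float(self.auc_roc)}


def binary_auc(scores, labels, class_name: str = "") -> AUCResult | None:
    """AUC_PR / AUC_ROC for pooled binary pixel labels.

    Returns ``None`` when the class has no positive (or no negative) pixels,
    in which case neither curve is defined.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = (np.asarray(labels).ravel() > 0).astype(np.int64)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    npos = int(labels.sum())
    if npos == 0 or npos == labels.size:
        return None
    precision, recall, _ = precision_recall_curve(labels, scores)
    fpr, tpr, _ = roc_curve(labels, scores)
    return AUCResult(
        class_name=class_name,
        auc_pr=float(average_precision_score(labels, scores)),
        auc_roc=float(roc_auc_score(labels, scores)),
        precision=precision, recall=recall, fpr=fpr, tpr=tpr)
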