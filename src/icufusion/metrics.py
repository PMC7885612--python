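"""Evaluation metrics for the imbalanced mortality task.

AUCPR (area under the precision-recall curve, step-wise interpolation, i.e.
average precision) is the headline metric under class imbalance; AUCROC is
reported alongside.  Ties in AUCROC get the Mann-Whitney half credit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def aucroc(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie); needs both classes present."""
    scores, labels = _validate(scores, labels)
    if labels.min() == labels.max():
        raise ValueError("AUCROC needs at least one positive and one negative")
    return float(roc_auc_score(labels, scores))


def aucpr(scores, labels) -> float:
    """Area under the PR curve with step-wise interpolation; needs >= 1 positive."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise ValueError("AUCPR needs at least one positive")
    return float(average_precision_score(labels, scores))


@dataclass
class MetricReport:
    aucpr: float
    aucroc: float
    n_pos: int
    n_neg: int

    @classmethod
    def from_predictions(cls, scores, labels) -> "MetricReport":
        scores, labels = _validate(scores, labels)
        return cls(
            aucpr=aucpr(scores, labels),
            aucroc=aucroc(scores, labels),
            n_pos=int(labels.sum()),
            n_neg=int((1 - labels).sum()),
        )

    def to_dict(self) -> dict:
        return {"aucpr": self.aucpr, "aucroc": self.aucroc,
                "n_pos": self.n_pos, "n_neg": self.n_neg}
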