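"""Ranking metrics for severely imbalanced classification.

AUROC is the probability that a random positive outranks a random negative
(ties counted 1/2); an uninformative scorer sits at 0.5 regardless of class
balance.  AUPRC is the step-wise average precision, whose uninformative
baseline is the positive base rate — which is what makes it the primary
metric at base rates of a few percent.  Linear interpolation of the PR curve
is deliberately avoided (it is known to be optimistic).
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .exceptions import ConfigurationError

__all__ = ["auroc", "auprc"]


def _validate(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ConfigurationError("scores and labels differ in length")
    if not np.all(np.isfinite(scores)):
        raise ConfigurationError("scores contain non-finite values")
    uniq = set(np.unique(labels).tolist())
    if not uniq <= {0, 1, 0.0, 1.0, False, True}:
        raise ConfigurationError("labels must be binary 0/1")
    return scores, labels.astype(int)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC; requires both classes present."""
    scores, labels = _validate(scores, labels)
    if labels.min() == labels.max():
        raise ConfigurationError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def auprc(scores, labels) -> float:
    """Step-wise average precision (no linear PR interpolation);
    requires at least one positive."""
    scores, labels = _validate(scores, labels)
    if labels.sum() == 0:
        raise ConfigurationError("AUPRC undefined: no positives present")
    return float(average_precision_score(labels, scores))
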