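"""Agreement metrics: ROC AUC, Cohen's kappa, sensitivity.

Self-contained implementations (the cross-validation engine depends on
them); each is pinned to a brute-force oracle in the test suite.  The
positive class throughout is the risk carrier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_matrix(predictions, labels, positive: int = 1) -> ConfusionMatrix:
    p = np.asarray(predictions) == positive
    y = np.asarray(labels) == positive
    return ConfusionMatrix(
        tp=int(np.sum(p & y)), fp=int(np.sum(p & ~y)),
        fn=int(np.sum(~p & y)), tn=int(np.sum(~p & ~y)))


def roc_auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties = 1/2).

    Computed via the rank-sum (Mann-Whitney) identity, which handles ties
    exactly with midranks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes to be present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def cohen_kappa(predictions, labels) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e).

    When both marginals are degenerate (p_e = 1) the statistic is undefined;
    it is reported as 0.0 with a warning.
    """
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.size == 0 or p.shape != y.shape:
        raise ValueError("predictions and labels must be non-empty, same length")
    n = p.size
    p_o = float(np.mean(p == y))
    classes = np.union1d(p, y)
    p_e = float(sum((np.mean(p == c)) * (np.mean(y == c)) for c in classes))
    if abs(1.0 - p_e) < 1e-15:
        warnings.warn("kappa undefined (degenerate marginals); reporting 0.0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def sensitivity(predictions, labels, positive: int = 1) -> float:
    """True-positive rate tp / (tp + fn) for the positive class."""
    cm = confusion_matrix(predictions, labels, positive=positive)
    if cm.tp + cm.fn == 0:
        raise ValueError("sensitivity undefined: no positive labels")
    return cm.tp / (cm.tp + cm.fn)


_LANDIS_KOCH = (
    (0.00, "slight"),       # [0.00, 0.20]
    (0.21, "fair"),         # [0.21, 0.40]
    (0.41, "moderate"),     # [0.41, 0.60]
    (0.61, "substantial"),  # [0.61, 0.80]
    (0.81, "almost perfect"),
)


def agreement_band(kappa: float) -> str:
    """Landis-Koch qualitative band; kappa rounded to 2 decimals first.

    Bands are closed on the left ([0.21, 0.40] -> "fair"); values below 0
    are "poor".
    """
    if not (-1.0 - 1e-9 <= kappa <= 1.0 + 1e-9):
        raise ValueError("kappa must lie in [-1, 1]")
    k = round(kappa, 2)
    if k < 0:
        return "poor"
    label = "slight"
    for lo, name in _LANDIS_KOCH:
        if k >= lo:
            label = name
    return label
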