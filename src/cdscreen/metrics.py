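"""Binary-classification performance metrics for pooled CV predictions.

Seven statistics: accuracy, AUC, correct classification rate (CCR, the
balanced accuracy — mean of sensitivity and specificity), sensitivity,
positive predictive value, specificity and negative predictive value.
AUC is the rank-based (Mann-Whitney, midranks for ties) area computed from
continuous scores.  Ratios with a zero denominator come back as NaN with a
warning rather than a silent zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    auc: float
    ccr: float
    sensitivity: float
    ppv: float
    specificity: float
    npv: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def confusion(true_labels, predicted_labels) -> ConfusionCounts:
    """Confusion counts for binary label arrays (1 = positive)."""
    t = np.asarray(true_labels).astype(int)
    p = np.asarray(predicted_labels).astype(int)
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != p.shape:
        raise ValueError("length mismatch")
    if not (np.isin(t, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        tp=int(((t == 1) & (p == 1)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        tn=int(((t == 0) & (p == 0)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def auc_score(true_labels, scores) -> float:
    """Rank-based AUC with midrank tie handling."""
    t = np.asarray(true_labels).astype(int)
    if len(np.unique(t)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(t, np.asarray(scores, dtype=float)))


def metrics_suite(true_labels, scores, predicted_labels=None, cutoff: float = 0.5) -> MetricsReport:
    """All seven statistics from pooled predictions.

    ``predicted_labels`` defaults to thresholding the scores at ``cutoff``.
    """
    t = np.asarray(true_labels).astype(int)
    s = np.asarray(scores, dtype=float)
    p = (s >= cutoff).astype(int) if predicted_labels is None else np.asarray(predicted_labels).astype(int)
    c = confusion(t, p)
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        auc=auc_score(t, s),
        ccr=(sens + spec) / 2,
        sensitivity=sens,
        ppv=_ratio(c.tp, c.tp + c.fp, "PPV"),
        specificity=spec,
        npv=_ratio(c.tn, c.tn + c.fn, "NPV"),
    )
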