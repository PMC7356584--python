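"""Threshold-specific binary classification datasets.

Each classifier targets one ln(Ks) decision threshold T (defaults 4.5, 5.0,
5.5).  Negatives are the records within 1.5 log units below T, i.e.
ln(Ks) in [T - 1.5, T); positives start at T (inclusive) and extend up to a
data-driven upper bound chosen so that the positive and negative class sizes
match as closely as possible; records above the bound, or below the
negative window, are excluded from that dataset.  The three datasets are
built independently of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (4.5, 5.0, 5.5)


@dataclass(frozen=True)
class ClassificationSpec:
    threshold: float
    negative_window: float = 1.5
    balance_rule: str = "scan-minimize"

    def __post_init__(self):
        if self.negative_window <= 0:
            raise ValueError("negative_window must be positive")


@dataclass
class LabeledDataset:
    """Feature matrix + binary labels for one threshold."""

    spec: ClassificationSpec
    features: pd.DataFrame
    labels: np.ndarray  # 1 = stable (positive), 0 = negative
    keys: list[str]
    ln_ks: np.ndarray
    positive_upper_bound: float = np.inf

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((1 - self.labels).sum())

    def composition(self) -> dict:
        return {
            "threshold": self.spec.threshold,
            "n_samples": len(self.labels),
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "positive_upper_bound": float(self.positive_upper_bound),
        }


def assign_class(ln_ks: float, spec: ClassificationSpec) -> str:
    """Classify one value: ``positive`` (>= threshold), ``negative``
    (within the window below), or ``excluded`` (below the window)."""
    if not np.isfinite(ln_ks):
        raise ValueError("ln_ks must be finite")
    if ln_ks >= spec.threshold:
        return "positive"
    if ln_ks >= spec.threshold - spec.negative_window:
        return "negative"
    return "excluded"


def balance_positive_bound(candidate_positives, n_negatives: int) -> float:
    """Upper ln(Ks) bound for the positive class balancing the two classes.

    Scans the sorted unique candidate values as bounds and returns the one
    minimizing |#positives kept - n_negatives|; ties break toward the larger
    bound (slight positive excess).
    """
    vals = np.asarray(sorted(candidate_positives), dtype=float)
    if vals.size == 0:
        raise ValueError("no candidate positives")
    best_u, best_cost = None, None
    for u in np.unique(vals):
        cost = abs(int((vals <= u).sum()) - n_negatives)
        if best_cost is None or cost < best_cost or (cost == best_cost and u > best_u):
            best_u, best_cost = float(u), cost
    return best_u


def build_dataset(
    records: pd.DataFrame, features: pd.DataFrame, spec: ClassificationSpec
) -> LabeledDataset:
    """Label one threshold's dataset from curated records + aligned features.

    ``records`` needs columns ``ln_ks`` and a key column (``guest_key`` +
    ``cd_key`` or ``key``); rows of ``features`` align positionally.
    """
    if len(records) != len(features):
        raise ValueError("records and features are not aligned")
    ln = records["ln_ks"].to_numpy(dtype=float)
    if "key" in records.columns:
        keys = records["key"].astype(str).tolist()
    else:
        keys = (records["guest_key"].astype(str) + "|" + records["cd_key"].astype(str)).tolist()
    # same pair measured under different conditions: disambiguate the keys
    seen: dict[str, int] = {}
    for i, k in enumerate(keys):
        seen[k] = seen.get(k, 0) + 1
        if seen[k] > 1:
            keys[i] = f"{k}#{seen[k]}"

    roles = np.array([assign_class(v, spec) for v in ln])
    neg_mask = roles == "negative"
    cand_mask = roles == "positive"
    if not cand_mask.any() or not neg_mask.any():
        raise ValueError(
            f"threshold {spec.threshold}: a class has zero members "
            f"({int(cand_mask.sum())} positive candidates, {int(neg_mask.sum())} negatives)"
        )
    bound = balance_positive_bound(ln[cand_mask], int(neg_mask.sum()))
    pos_mask = cand_mask & (ln <= bound)
    keep = neg_mask | pos_mask
    idx = np.flatnonzero(keep)
    return LabeledDataset(
        spec=spec,
        features=features.iloc[idx].reset_index(drop=True),
        labels=pos_mask[idx].astype(int),
        keys=[keys[i] for i in idx],
        ln_ks=ln[idx],
        positive_upper_bound=bound,
    )


def build_datasets(
    records: pd.DataFrame,
    features: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    negative_window: float = 1.5,
) -> dict[float, LabeledDataset]:
    """One independently-built :class:`LabeledDataset` per threshold."""
    return {
        t: build_dataset(records, features, ClassificationSpec(t, negative_window))
        for t in thresholds
    }
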