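"""Consensus screening of candidate guest-cyclodextrin systems.

Three threshold-specific classifiers (ln(Ks) >= 4.5, 5.0, 5.5) each vote on
a candidate system; a system is flagged *promising* only when all three
predict the stable class.  In validation mode, predictions are compared
with measured ln(Ks) values: the actual class at threshold T is
``measured >= T`` (same inclusivity as training), and the agreement report
counts correct predictions over systems x thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cd_features import SystemFeaturizer
from .class_builder import DEFAULT_THRESHOLDS
from .qspr import StabilityClassifier


@dataclass
class CandidateVerdict:
    guest_key: str
    cd_key: str
    thresholds: list[float]
    scores: list[float]
    predicted: list[int]  # 1 = stable at that threshold
    measured_ln_ks: float | None = None

    @property
    def promising(self) -> bool:
        return all(p == 1 for p in self.predicted)

    @property
    def mean_score(self) -> float:
        return float(np.mean(self.scores))


# Published experimental validation set: cefuroxime axetil (CA) against five
# pharmaceutically common CDs, with measured ln(Ks) and the three
# threshold-model votes reported for each system.
CEFUROXIME_AXETIL_VALIDATION = pd.DataFrame(
    {
        "cd_key": ["alphaCD", "betaCD", "hydroxypropyl-alphaCD", "hydroxypropyl-betaCD", "methyl-betaCD"],
        "measured_ln_ks": [4.63, 5.72, 4.72, 5.98, 5.76],
        "pred_4.5": [1, 1, 1, 1, 1],
        "pred_5.0": [0, 1, 0, 1, 1],
        "pred_5.5": [0, 1, 0, 0, 1],
    }
)


def cefuroxime_axetil_verdicts() -> list[CandidateVerdict]:
    """The published five-system validation set as verdict objects."""
    out = []
    for _, row in CEFUROXIME_AXETIL_VALIDATION.iterrows():
        preds = [int(row[f"pred_{t}"]) for t in DEFAULT_THRESHOLDS]
        out.append(
            CandidateVerdict(
                guest_key="cefuroxime-axetil",
                cd_key=row["cd_key"],
                thresholds=list(DEFAULT_THRESHOLDS),
                scores=[float(p) for p in preds],
                predicted=preds,
                measured_ln_ks=float(row["measured_ln_ks"]),
            )
        )
    return out


@dataclass
class ConsensusScreen:
    """Three fitted threshold models plus the shared featurizer."""

    featurizer: SystemFeaturizer
    models: dict[float, StabilityClassifier]

    def __post_init__(self):
        if not self.models:
            raise ValueError("no models supplied")

    def predict_system(self, guest_structure: str, cd_spec: str) -> CandidateVerdict:
        """Featurize the pair once and apply every threshold model."""
        X = self.featurizer.transform([(guest_structure, cd_spec)])
        thresholds = sorted(self.models)
        scores, predicted = [], []
        for t in thresholds:
            m = self.models[t]
            s = float(m.predict_proba(X)[0, 1])
            scores.append(s)
            predicted.append(int(s >= m.cutoff))
        return CandidateVerdict(
            guest_key=guest_structure, cd_key=cd_spec,
            thresholds=thresholds, scores=scores, predicted=predicted,
        )

    def screen_library(self, guest_structure: str, cd_library) -> list[CandidateVerdict]:
        """Verdicts for one guest against a CD library, best first.

        Sorted by (promising desc, mean score desc, cd key) — the last term
        makes ties deterministic.
        """
        cd_library = list(cd_library)
        if not cd_library:
            raise ValueError("empty CD library")
        verdicts = [self.predict_system(guest_structure, cd) for cd in cd_library]
        verdicts.sort(key=lambda v: (-int(v.promising), -v.mean_score, v.cd_key))
        return verdicts


def predict_system(guest_structure: str, cd_spec: str, featurizer, models3) -> CandidateVerdict:
    return ConsensusScreen(featurizer, models3).predict_system(guest_structure, cd_spec)


def screen_library(guest_structure: str, cd_library, featurizer, models3) -> list[CandidateVerdict]:
    return ConsensusScreen(featurizer, models3).screen_library(guest_structure, cd_library)


def evaluate_against_experiment(
    verdicts: list[CandidateVerdict], measured_ln_ks=None
) -> dict:
    """Compare per-threshold predictions with measured ln(Ks) values.

    The actual class at threshold T is ``measured >= T``.  Returns counts
    and the fraction of correct predictions over systems x thresholds,
    plus a per-system breakdown; invariant to system ordering.
    """
    if measured_ln_ks is None:
        measured = [v.measured_ln_ks for v in verdicts]
    else:
        measured = list(measured_ln_ks)
    if any(m is None for m in measured):
        raise ValueError("every verdict needs a measured ln(Ks)")
    per_system = []
    n_total = n_correct = 0
    for v, m in zip(verdicts, measured):
        actual = [int(m >= t) for t in v.thresholds]
        correct = [int(a == p) for a, p in zip(actual, v.predicted)]
        n_total += len(correct)
        n_correct += sum(correct)
        per_system.append(
            {"guest_key": v.guest_key, "cd_key": v.cd_key, "measured_ln_ks": m,
             "actual": actual, "predicted": v.predicted, "n_correct": sum(correct)}
        )
    per_system.sort(key=lambda d: (d["guest_key"], d["cd_key"]))
    return {
        "n_predictions": n_total,
        "n_correct": n_correct,
        "percent_correct": 100.0 * n_correct / n_total,
        "n_promising": sum(v.promising for v in verdicts),
        "systems": per_system,
    }


def verdicts_to_frame(verdicts: list[CandidateVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        row = {"guest": v.guest_key, "cd": v.cd_key, "promising": v.promising,
               "mean_score": v.mean_score}
        for t, s, p in zip(v.thresholds, v.scores, v.predicted):
            row[f"score_{t}"] = s
            row[f"pred_{t}"] = p
        if v.measured_ln_ks is not None:
            row["measured_ln_ks"] = v.measured_ln_ks
        rows.append(row)
    return pd.DataFrame(rows)
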