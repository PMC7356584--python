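"""Gradient-boosted stability classifiers with external cross-validation.

The learner is LightGBM behind a scikit-learn estimator.  Hyperparameters
are chosen by an internal 5-fold grid search maximizing AUC; honest
generalization estimates come from 5-fold *external* cross-validation, in
which each held-out fold is scored by a model whose entire training —
including the grid search — never saw that fold.  Out-of-fold predictions
are pooled into a :class:`PredictionSet` for metric calculation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .class_builder import ClassificationSpec, LabeledDataset
from .metrics import MetricsReport, metrics_suite

DEFAULT_GRID = {
    "n_estimators": [100, 300],
    "num_leaves": [7, 31],
    "learning_rate": [0.1],
    "min_child_samples": [5, 20],
}


def split_folds(keys, k: int = 5, seed: int = 0) -> dict[str, int]:
    """Assign record keys to k folds of nearly equal size (|diff| <= 1).

    A pure function of the *set* of keys, k and seed: input order never
    changes the assignment (keys are sorted before the seeded shuffle).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    keys = sorted(map(str, keys))
    if len(keys) < k:
        raise ValueError(f"need at least {k} records for {k} folds")
    order = np.random.default_rng(seed).permutation(len(keys))
    return {keys[j]: int(i % k) for i, j in enumerate(order)}


def _base_learner(hyperparams: dict, seed: int) -> lgb.LGBMClassifier:
    return lgb.LGBMClassifier(
        random_state=seed,
        deterministic=True,
        n_jobs=1,
        verbose=-1,
        **hyperparams,
    )


def train_learner(features, labels, hyperparams: dict, seed: int = 0) -> lgb.LGBMClassifier:
    """Fit one gradient-boosted classifier; deterministic under the seed."""
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single_class: both classes must be present for training")
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(
            np.asarray(features, dtype=float),
            columns=[f"f{i}" for i in range(np.asarray(features).shape[1])],
        )
    model = _base_learner(hyperparams, seed)
    model.fit(features, y)
    return model


class StabilityClassifier(BaseEstimator, ClassifierMixin):
    """Grid-searched gradient-boosted binary stability classifier.

    ``fit`` runs an internal k-fold grid search (AUC-scored) over
    ``param_grid`` and refits the best configuration on all data — ties go
    to the first grid point in deterministic iteration order.

    Parameters
    ----------
    param_grid : dict, optional
        LightGBM hyperparameter grid (default: 8 points).
    internal_cv_folds : int
        Folds of the internal selection CV (default 5).
    random_state : int
        Seed for fold shuffling and tree building.
    cutoff : float
        Score threshold mapping probabilities to labels (default 0.5).
    stratified : bool
        Stratify the internal CV folds (useful for small sets).

    Attributes
    ----------
    best_params_ : dict
        Winning hyperparameters.
    feature_names_ : list of str
        Training feature schema, enforced at prediction time.
    booster_ : lightgbm.Booster
        The fitted ensemble.
    """

    def __init__(
        self,
        param_grid: dict | None = None,
        internal_cv_folds: int = 5,
        random_state: int = 0,
        cutoff: float = 0.5,
        stratified: bool = False,
    ):
        self.param_grid = param_grid
        self.internal_cv_folds = internal_cv_folds
        self.random_state = random_state
        self.cutoff = cutoff
        self.stratified = stratified

    def _grid(self) -> dict:
        return self.param_grid if self.param_grid is not None else DEFAULT_GRID

    def fit(self, X, y):
        Xa = self._to_frame(X, learn_schema=True)
        y = np.asarray(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("single_class: both classes must be present for training")
        grid = self._grid()
        n_points = int(np.prod([len(v) for v in grid.values()]))
        if n_points == 1:
            self.best_params_ = {k: v[0] for k, v in grid.items()}
        else:
            cv_cls = StratifiedKFold if self.stratified else KFold
            search = GridSearchCV(
                _base_learner({}, self.random_state),
                grid,
                scoring="roc_auc",
                cv=cv_cls(self.internal_cv_folds, shuffle=True, random_state=self.random_state),
                refit=False,
                n_jobs=1,
            )
            search.fit(Xa, y)
            self.best_params_ = search.best_params_
        self.model_ = train_learner(Xa, y, self.best_params_, self.random_state)
        self.classes_ = np.array([0, 1])
        return self

    def _to_frame(self, X, learn_schema: bool = False) -> pd.DataFrame:
        """Validate against the training feature schema; returns a named frame."""
        if isinstance(X, pd.DataFrame):
            if learn_schema:
                self.feature_names_ = list(X.columns)
                return X.astype(float)
            missing = [c for c in self.feature_names_ if c not in X.columns]
            if missing:
                raise ValueError(f"schema_mismatch: missing features {missing[:5]}")
            return X[self.feature_names_].astype(float)
        Xa = np.asarray(X, dtype=float)
        if learn_schema:
            self.feature_names_ = [f"f{i}" for i in range(Xa.shape[1])]
        elif Xa.shape[1] != len(self.feature_names_):
            raise ValueError("schema_mismatch: feature count differs from training")
        return pd.DataFrame(Xa, columns=self.feature_names_)

    @property
    def booster_(self) -> lgb.Booster:
        return self.model_.booster_

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        p1 = self.model_.predict_proba(self._to_frame(X))[:, 1]
        return np.column_stack([1 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= self.cutoff).astype(int)

    # -- persistence (text artifacts: booster string + JSON manifest) -------

    def save(self, directory: str | Path, class_spec: ClassificationSpec | None = None) -> Path:
        check_is_fitted(self, "model_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        model_txt = self.booster_.model_to_string()
        (directory / "model.txt").write_text(model_txt)
        manifest = {
            "best_params": self.best_params_,
            "random_state": self.random_state,
            "cutoff": self.cutoff,
            "internal_cv_folds": self.internal_cv_folds,
            "feature_names": self.feature_names_,
            "class_spec": None
            if class_spec is None
            else {
                "threshold": class_spec.threshold,
                "negative_window": class_spec.negative_window,
                "balance_rule": class_spec.balance_rule,
            },
            "model_digest": hashlib.sha256(model_txt.encode()).hexdigest(),
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "StabilityClassifier":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        est = cls(
            param_grid={k: [v] for k, v in manifest["best_params"].items()},
            internal_cv_folds=manifest["internal_cv_folds"],
            random_state=manifest["random_state"],
            cutoff=manifest["cutoff"],
        )
        est.best_params_ = manifest["best_params"]
        est.feature_names_ = manifest["feature_names"]
        est.classes_ = np.array([0, 1])
        booster = lgb.Booster(model_str=(directory / "model.txt").read_text())
        est.model_ = _BoosterAdapter(booster)
        return est


class _BoosterAdapter:
    """Duck-typed stand-in for LGBMClassifier built from a reloaded booster."""

    def __init__(self, booster: lgb.Booster):
        self.booster_ = booster

    def predict_proba(self, X) -> np.ndarray:
        p1 = self.booster_.predict(np.asarray(X, dtype=float))
        return np.column_stack([1 - p1, p1])


def grid_search(features, labels, config: "LearnerConfig | None" = None, **kwargs) -> dict:
    """Best hyperparameters by internal-CV AUC (thin wrapper)."""
    cfg = config or LearnerConfig(**kwargs)
    est = cfg.make_estimator()
    est.fit(features, labels)
    return est.best_params_


@dataclass
class LearnerConfig:
    param_grid: dict | None = None
    internal_cv_folds: int = 5
    seed: int = 0
    cutoff: float = 0.5
    stratified: bool = False

    def make_estimator(self) -> StabilityClassifier:
        return StabilityClassifier(
            param_grid=self.param_grid,
            internal_cv_folds=self.internal_cv_folds,
            random_state=self.seed,
            cutoff=self.cutoff,
            stratified=self.stratified,
        )


def external_cv(
    dataset: LabeledDataset, config: LearnerConfig | None = None, k: int = 5
) -> pd.DataFrame:
    """Pooled out-of-fold predictions from k-fold external cross-validation.

    For each fold, a fresh grid-searched classifier is trained on the other
    folds and scores the held-out records; every record is predicted exactly
    once by a model that never saw it.  Returns a PredictionSet frame with
    columns ``key, y_true, score, y_pred, fold``.
    """
    cfg = config or LearnerConfig()
    assignment = split_folds(dataset.keys, k=k, seed=cfg.seed)
    folds = np.array([assignment[str(key)] for key in dataset.keys])
    rows = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        y_train = dataset.labels[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(
                f"fold {fold}: training split has a single class; enable stratified folds"
            )
        est = cfg.make_estimator()
        est.fit(dataset.features.iloc[train], y_train)
        assert not np.any(test & train), "external-CV purity violated"
        scores = est.predict_proba(dataset.features.iloc[test])[:, 1]
        for key, y, s in zip(
            np.array(dataset.keys, dtype=object)[test], dataset.labels[test], scores
        ):
            rows.append(
                {"key": key, "y_true": int(y), "score": float(s),
                 "y_pred": int(s >= cfg.cutoff), "fold": fold}
            )
    out = pd.DataFrame(rows).sort_values("key", kind="stable").reset_index(drop=True)
    assert len(out) == len(dataset.keys) and out["key"].is_unique
    return out


def evaluate_prediction_set(pred: pd.DataFrame, cutoff: float = 0.5) -> MetricsReport:
    return metrics_suite(pred["y_true"], pred["score"], pred["y_pred"], cutoff=cutoff)


def fit_final(
    dataset: LabeledDataset, config: LearnerConfig | None = None
) -> StabilityClassifier:
    """Grid search on the full dataset, then refit on everything."""
    cfg = config or LearnerConfig()
    est = cfg.make_estimator()
    est.fit(dataset.features, dataset.labels)
    return est
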