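"""Fold splitting, grid-searched learner, external CV purity, persistence."""

import numpy as np
import pandas as pd
import pytest

import cdscreen as cs
from cdscreen.class_builder import ClassificationSpec, LabeledDataset
from cdscreen.qspr import (
    LearnerConfig,
    StabilityClassifier,
    external_cv,
    fit_final,
    split_folds,
    train_learner,
)


def toy_dataset(n=100, n_features=4, seed=0, informative=True):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, n_features)),
                     columns=[f"x{i}" for i in range(n_features)])
    if informative:
        y = (X["x0"] + 0.3 * rng.normal(size=n) > 0).astype(int).to_numpy()
    else:
        y = rng.integers(0, 2, n)
        y[:2] = [0, 1]
    return LabeledDataset(
        spec=ClassificationSpec(5.0), features=X, labels=y,
        keys=[f"k{i}" for i in range(n)], ln_ks=np.full(n, 5.0),
    )


SMALL_GRID = {"n_estimators": [50], "num_leaves": [7, 15], "min_child_samples": [2]}


class TestSplitFolds:
    @pytest.mark.parametrize("n,k,sizes", [(10, 5, {2}), (11, 5, {2, 3})])
    def test_nearly_equal_sizes(self, n, k, sizes):
        folds = split_folds([f"k{i}" for i in range(n)], k=k, seed=0)
        counts = np.bincount(list(folds.values()), minlength=k)
        assert set(counts.tolist()) <= sizes and counts.sum() == n

    def test_pure_function_of_keys_and_seed(self):
        keys = [f"k{i}" for i in range(20)]
        a = split_folds(keys, seed=3)
        b = split_folds(list(reversed(keys)), seed=3)
        assert a == b
        assert split_folds(keys, seed=4) != a

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            split_folds(["a", "b"], k=1)


class TestLearner:
    def test_separable_data_fit_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.3, (10, 2)), rng.normal(3, 0.3, (10, 2))])
        y = np.repeat([0, 1], 10)
        model = train_learner(X, y, {"n_estimators": 200, "min_child_samples": 1, "num_leaves": 3}, seed=0)
        assert (model.predict(pd.DataFrame(X, columns=["f0", "f1"])) == y).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single_class"):
            train_learner(np.zeros((10, 2)), np.ones(10), {})

    def test_refit_deterministic(self):
        ds = toy_dataset()
        scores = []
        for _ in range(2):
            est = StabilityClassifier(param_grid=SMALL_GRID, random_state=7).fit(
                ds.features, ds.labels
            )
            scores.append(est.predict_proba(ds.features)[:, 1])
        np.testing.assert_array_equal(scores[0], scores[1])


class TestGridSearch:
    def test_single_point_grid_short_circuits(self):
        ds = toy_dataset(40)
        grid = {"n_estimators": [25], "num_leaves": [7]}
        est = StabilityClassifier(param_grid=grid).fit(ds.features, ds.labels)
        assert est.best_params_ == {"n_estimators": 25, "num_leaves": 7}

    def test_strong_setting_beats_planted_underfit(self):
        # a single decision stump cannot express the additive 3-feature
        # signal; a boosted stump ensemble can
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(300, 3)), columns=["a", "b", "c"])
        y = ((X["a"] + X["b"] + X["c"]) > 0).astype(int).to_numpy()
        grid = {"n_estimators": [1, 200], "num_leaves": [2], "min_child_samples": [2]}
        est = StabilityClassifier(param_grid=grid, random_state=0).fit(X, y)
        assert est.best_params_["n_estimators"] == 200


class TestExternalCV:
    def test_every_record_predicted_once_with_balanced_folds(self):
        ds = toy_dataset(100)
        pred = external_cv(ds, LearnerConfig(param_grid=SMALL_GRID, seed=0))
        assert len(pred) == 100 and pred["key"].is_unique
        assert sorted(np.bincount(pred["fold"])) == [20, 20, 20, 20, 20]

    def test_planted_signal_recovered(self):
        ds = toy_dataset(150, seed=1)
        pred = external_cv(ds, LearnerConfig(param_grid=SMALL_GRID, seed=1))
        rep = cs.evaluate_prediction_set(pred)
        assert rep.auc > 0.8

    def test_permuted_labels_score_near_chance(self):
        ds = toy_dataset(150, seed=2, informative=False)
        pred = external_cv(ds, LearnerConfig(param_grid=SMALL_GRID, seed=2))
        assert 0.35 < cs.evaluate_prediction_set(pred).auc < 0.65

    def test_input_order_does_not_change_pooled_predictions(self):
        ds = toy_dataset(60, seed=3)
        perm = np.random.default_rng(0).permutation(60)
        ds2 = LabeledDataset(
            spec=ds.spec, features=ds.features.iloc[perm].reset_index(drop=True),
            labels=ds.labels[perm], keys=[ds.keys[i] for i in perm], ln_ks=ds.ln_ks[perm],
        )
        cfg = LearnerConfig(param_grid={"n_estimators": [30], "num_leaves": [7], "min_child_samples": [2]}, seed=5)
        p1 = external_cv(ds, cfg)
        p2 = external_cv(ds2, cfg)
        pd.testing.assert_frame_equal(p1, p2)


class TestFinalModel:
    def test_serialization_round_trip_bit_identical(self, tmp_path):
        ds = toy_dataset(80)
        est = fit_final(ds, LearnerConfig(param_grid=SMALL_GRID, seed=0))
        est.save(tmp_path / "m", class_spec=ds.spec)
        reloaded = StabilityClassifier.load(tmp_path / "m")
        probe = ds.features.iloc[:20]
        np.testing.assert_array_equal(
            est.predict_proba(probe), reloaded.predict_proba(probe)
        )

    def test_training_score_at_least_external_cv(self):
        ds = toy_dataset(120, seed=4)
        cfg = LearnerConfig(param_grid=SMALL_GRID, seed=4)
        cv_acc = (external_cv(ds, cfg)["y_pred"] == external_cv(ds, cfg)["y_true"]).mean()
        est = fit_final(ds, cfg)
        train_acc = (est.predict(ds.features) == ds.labels).mean()
        assert train_acc >= cv_acc - 1e-12

    def test_missing_feature_at_predict_time(self):
        ds = toy_dataset(40)
        est = fit_final(ds, LearnerConfig(param_grid={"n_estimators": [20], "num_leaves": [7], "min_child_samples": [2]}))
        with pytest.raises(ValueError, match="schema_mismatch"):
            est.predict(ds.features.drop(columns=["x0"]))
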