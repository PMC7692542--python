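"""Median split, partitioning, feature selection, classifiers, evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dyadsync.config import ConfigError, PipelineConfig
from dyadsync.core import DataError
from dyadsync.classify import (
    cross_validate_model,
    evaluate,
    fit_mlp,
    fit_random_forest,
    make_split,
    median_split,
    run_classification,
)
from dyadsync.selection import CFSSelector, SVMRFESelector, cfs_merit


class TestMedianSplit:
    def test_even_split(self):
        labels = median_split([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        labels = median_split([1, 2, 2, 5])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_group_size_gap_bounded_by_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            scores = rng.integers(1, 8, 40).astype(float)
            labels = median_split(scores)
            n_tied = int(np.sum(scores == np.median(scores)))
            gap = abs(int(np.sum(labels == "high")) - int(np.sum(labels == "low")))
            # ties all go low, so the imbalance is bounded by the tie count
            # on both sides of an even-n median (zero ties -> exact balance)
            assert gap <= 2 * n_tied if n_tied else gap == 0

    def test_degenerate_scores_rejected(self):
        with pytest.raises(DataError):
            median_split([3.0, 3.0, 3.0])


class TestMakeSplit:
    def _cohort(self, n=100):
        ids = [f"p{i}" for i in range(n)]
        groups = [f"d{i // 2}" for i in range(n)]
        labels = np.array(["high", "low"] * (n // 2))
        return ids, labels, groups

    def test_seventy_thirty_sizes(self):
        ids, labels, groups = self._cohort()
        plan = make_split(ids, labels, groups, 0.7, seed=1)
        assert abs(len(plan.train_ids) - 70) <= 2
        assert len(plan.train_ids) + len(plan.test_ids) == 100

    def test_same_seed_identical_plan(self):
        ids, labels, groups = self._cohort()
        p1 = make_split(ids, labels, groups, 0.7, seed=5)
        p2 = make_split(ids, labels, groups, 0.7, seed=5)
        assert p1.train_ids == p2.train_ids and p1.folds == p2.folds

    def test_dyads_never_separated(self):
        ids, labels, groups = self._cohort()
        plan = make_split(ids, labels, groups, 0.7, seed=2)
        group_of = dict(zip(ids, groups))
        train_groups = {group_of[i] for i in plan.train_ids}
        test_groups = {group_of[i] for i in plan.test_ids}
        assert not train_groups & test_groups
        # and folds keep dyads together too
        for g in train_groups:
            folds = {plan.folds[i] for i in plan.train_ids if group_of[i] == g}
            assert len(folds) == 1

    def test_folds_partition_training_ids(self):
        ids, labels, groups = self._cohort()
        plan = make_split(ids, labels, groups, 0.7, seed=3, cv_folds=5)
        assert set(plan.folds) == set(plan.train_ids)
        assert set(plan.folds.values()) == set(range(5))

    def test_participant_level_mode_stratifies(self):
        ids, labels, _ = self._cohort()
        plan = make_split(ids, labels, None, 0.7, seed=4, group_by_dyad=False)
        lab = dict(zip(ids, labels))
        train_high = sum(lab[i] == "high" for i in plan.train_ids)
        assert abs(train_high - 35) <= 1


class TestCFS:
    def test_selects_perfect_feature_over_duplicate_and_noise(self):
        rng = np.random.default_rng(7)
        y = np.tile([0.0, 1.0], 50)
        a = y.copy()
        b = y.copy()                      # redundant duplicate
        c = rng.normal(size=100)          # noise
        X = np.column_stack([c, a, b])
        sel = CFSSelector().fit(X, y)
        assert list(sel.selected_) == [1]
        # exhaustive merit check over all non-empty subsets of size <= 3
        yz = (y - y.mean()) / y.std()
        Xz = (X - X.mean(0)) / X.std(0)
        r_cf = np.abs(Xz.T @ yz / len(y))
        r_ff = np.abs(Xz.T @ Xz / len(y))
        best = max(
            (subset for k in (1, 2, 3)
             for subset in itertools.combinations(range(3), k)),
            key=lambda s: cfs_merit(r_cf, r_ff, list(s)),
        )
        assert cfs_merit(r_cf, r_ff, [1]) == pytest.approx(
            cfs_merit(r_cf, r_ff, list(best)))

    def test_single_perfect_feature_has_unit_merit(self):
        y = np.tile([0.0, 1.0], 20)
        sel = CFSSelector().fit(y[:, None], y)
        assert sel.merit_ == pytest.approx(1.0)

    def test_pure_noise_yields_near_zero_merit(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(2000, 10))
        y = np.tile([0.0, 1.0], 1000)
        sel = CFSSelector().fit(X, y)
        assert sel.merit_ < 0.15  # vs 1.0 for a single perfect feature

    def test_transform_drops_unselected_columns(self):
        y = np.tile([0.0, 1.0], 30)
        X = np.column_stack([y, np.zeros(60) + 1e-12])
        sel = CFSSelector().fit(X, y)
        assert sel.transform(X).shape[1] == len(sel.selected_)


class TestSVMRFE:
    def test_informative_feature_survives(self):
        survived = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x1 = rng.normal(size=200)
            y = (x1 > 0).astype(float)
            X = np.column_stack([x1] + [rng.normal(size=200) for _ in range(9)])
            sel = SVMRFESelector(target_k=3, random_state=seed).fit(X, y)
            survived += 0 in sel.selected_
        assert survived >= 19

    def test_target_k_equal_to_feature_count_is_identity(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 5))
        y = np.tile([0.0, 1.0], 25)
        sel = SVMRFESelector(target_k=5).fit(X, y)
        assert list(sel.selected_) == [0, 1, 2, 3, 4]

    def test_duplicated_informative_features_drop_before_noise_only_once(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = (x > 0).astype(float)
        X = np.column_stack([x, x.copy(), rng.normal(size=300) * 1e-2])
        sel = SVMRFESelector(target_k=2).fit(X, y)
        # one duplicate may go, but an informative copy must remain
        assert 0 in sel.selected_ or 1 in sel.selected_


class TestClassifiers:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        y = np.where(X[:, 0] + 0.2 * X[:, 1] > 0, "high", "low")
        return X, y

    def test_random_forest_learns_separable_toy(self, pipe_cfg):
        X, y = self._separable()
        model = fit_random_forest(X, y, pipe_cfg.random_forest)
        assert np.mean(model.predict(X) == y) >= 0.95

    def test_random_forest_deterministic(self, pipe_cfg):
        X, y = self._separable(seed=3)
        p1 = fit_random_forest(X, y, pipe_cfg.random_forest).predict(X)
        p2 = fit_random_forest(X, y, pipe_cfg.random_forest).predict(X)
        assert np.array_equal(p1, p2)

    def test_single_class_labels_rejected(self, pipe_cfg):
        X = np.zeros((10, 2))
        with pytest.raises(DataError):
            fit_random_forest(X, np.array(["low"] * 10), pipe_cfg.random_forest)

    def test_unknown_hyperparameter_rejected(self):
        with pytest.raises(ConfigError):
            fit_random_forest(np.zeros((4, 1)), np.array(["a", "b", "a", "b"]),
                              {"n_trees": 5})

    def test_mlp_learns_xor_blobs(self, pipe_cfg):
        rng = np.random.default_rng(4)
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]])
        X = np.vstack([c + 0.1 * rng.normal(size=(2000, 2)) for c in centers])
        y = np.array(["high"] * 4000 + ["low"] * 4000)
        model = fit_mlp(X, y, pipe_cfg.mlp)
        assert np.mean(model.predict(X) == y) >= 0.9

    def test_mlp_deterministic(self, pipe_cfg):
        X, y = self._separable(seed=5)
        m1 = fit_mlp(X, y, pipe_cfg.mlp)
        m2 = fit_mlp(X, y, pipe_cfg.mlp)
        w1 = m1.named_steps["mlp"].coefs_[0]
        w2 = m2.named_steps["mlp"].coefs_[0]
        np.testing.assert_array_equal(w1, w2)


class TestCrossValidate:
    def test_perfectly_learnable_toy(self, pipe_cfg):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 1))
        y = np.where(X[:, 0] > 0, "high", "low")
        folds = np.arange(100) % 5
        fit = lambda Xf, yf: fit_random_forest(Xf, yf, pipe_cfg.random_forest)
        mean, sd, accs = cross_validate_model(fit, X, y, folds)
        assert mean == 1.0 and sd == 0.0 and len(accs) == 5

    def test_reported_sd_is_sd_of_fold_accuracies(self, pipe_cfg):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(120, 3))
        y = np.where(X[:, 0] + rng.normal(size=120) > 0, "high", "low")
        folds = np.arange(120) % 5
        fit = lambda Xf, yf: fit_random_forest(Xf, yf, pipe_cfg.random_forest)
        mean, sd, accs = cross_validate_model(fit, X, y, folds)
        assert sd == pytest.approx(np.std(accs))


class TestEvaluate:
    class _Fixed:
        def __init__(self, pred):
            self._pred = np.asarray(pred)

        def predict(self, X):
            return self._pred

    def test_majority_baseline_from_test_labels(self):
        y = np.array(["high"] * 37 + ["low"] * 35)
        ev = evaluate(self._Fixed(y), np.zeros((72, 1)), y)
        assert ev["majority_baseline"] == pytest.approx(37 / 72)
        assert round(100 * ev["majority_baseline"], 2) == 51.39

    def test_perfect_predictions(self):
        y = np.array(["high", "low", "high", "low"])
        ev = evaluate(self._Fixed(y), np.zeros((4, 1)), y)
        assert ev["accuracy"] == 1.0
        assert ev["sensitivity"] == 1.0 and ev["specificity"] == 1.0

    def test_predict_all_high_on_balanced_labels(self):
        y = np.array(["high", "low"] * 10)
        ev = evaluate(self._Fixed(np.array(["high"] * 20)), np.zeros((20, 1)), y)
        assert ev["sensitivity"] == 1.0 and ev["specificity"] == 0.0
        assert ev["confusion"]["fn"] == 0 and ev["confusion"]["tn"] == 0

    def test_empty_test_set_rejected(self):
        with pytest.raises(DataError):
            evaluate(self._Fixed([]), np.zeros((0, 1)), np.array([]))


class TestRunClassification:
    def test_protocol_on_informative_table(self, pipe_cfg):
        rng = np.random.default_rng(9)
        n = 120
        latent = np.repeat(rng.normal(size=n // 2), 2)  # dyad-level signal
        table = pd.DataFrame({
            "dyad_id": np.repeat([f"d{i}" for i in range(n // 2)], 2),
            "attraction": 4.5 + latent + 0.2 * rng.normal(size=n),
            "gender": rng.integers(0, 2, n).astype(float),
        }, index=[f"p{i}" for i in range(n)])
        for j in range(30):
            beta = 1.0 if j < 5 else 0.0
            table[f"f{j}"] = beta * latent + rng.normal(size=n)
        reports = run_classification(table, pipe_cfg, seed=0)
        assert set(reports) == {"random_forest", "mlp"}
        for rep in reports.values():
            assert rep.test_accuracy > rep.majority_baseline
            assert rep.cv_sd == pytest.approx(np.std(rep.fold_accuracies))
            c = rep.confusion
            total = sum(c.values())
            assert rep.test_accuracy == pytest.approx(
                (c["tp"] + c["tn"]) / total)
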