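"""The stacked classifier: preprocessing, base learners, meta-network, stack."""

import math

import numpy as np
import pytest

from adaptabench import (
    Roster,
    build_mlr,
    fit_base_learners,
    fit_deepdili,
    fit_meta_network,
    fit_preprocessor,
    load_model,
    save_model,
    select_base_learners,
)
from adaptabench.ensemble import (
    MetaConfig,
    TrainedBaseLearner,
    fast_config,
)
from adaptabench.metrics import confusion_counts, scalar_metrics

from conftest import separable_roster, tiny_ensemble_config, toy_roster  # noqa: F401


def _split_roster(roster, n_train):
    idx = np.arange(len(roster))
    return roster.subset(idx[:n_train]), roster.subset(idx[n_train:])


class TestPreprocessor:
    def test_constant_column_dropped(self):
        r = toy_roster(n=10, n_desc=3)
        desc = r.descriptors.copy()
        desc[:, 1] = 7.0
        r = Roster(r.drug_ids, r.approval_years, r.labels, desc, r.descriptor_names)
        pre = fit_preprocessor(r)
        assert pre.kept_names == ("d0", "d2")

    def test_training_matrix_standardized(self):
        r = toy_roster(n=50, n_desc=4, seed=2)
        pre = fit_preprocessor(r)
        Z = pre.transform(r)
        assert np.abs(Z.mean(axis=0)).max() < 1e-9
        assert np.abs(Z.var(axis=0) - 1).max() < 1e-6

    def test_transform_uses_training_statistics(self):
        # hand-computed: train column has mean 1.0, sd 1.0
        train = Roster(["a", "b"], [1990, 1991], [0, 1], [[0.0], [2.0]], ["d"])
        other = Roster(["c", "d"], [1992, 1993], [0, 1], [[4.0], [6.0]], ["d"])
        pre = fit_preprocessor(train)
        assert pre.transform(other).ravel() == pytest.approx([3.0, 5.0])

    def test_all_constant_descriptors_degenerate(self):
        r = Roster(["a", "b"], [1990, 1991], [0, 1], [[1.0], [1.0]], ["d"])
        with pytest.raises(ValueError):
            fit_preprocessor(r)

    def test_namespace_mismatch_rejected(self):
        pre = fit_preprocessor(toy_roster(n=10, n_desc=3))
        with pytest.raises(ValueError):
            pre.transform(toy_roster(n=4, n_desc=2))


class TestBaseLearners:
    def test_one_candidate_per_family_grid_point(self, separable_roster):
        train, valid = _split_roster(separable_roster, 300)
        cands = fit_base_learners(train, valid, fast_config(seed=0))
        assert len(cands) == 5
        assert [c.family for c in cands] == [
            "knn", "logistic_regression", "svm", "random_forest", "xgboost",
        ]

    def test_separable_data_high_validation_mcc(self, separable_roster):
        train, valid = _split_roster(separable_roster, 300)
        cands = fit_base_learners(train, valid, fast_config(seed=0))
        assert all(c.validation_mcc > 0.9 for c in cands)

    def test_permuted_validation_labels_destroy_signal(self, separable_roster):
        train, valid = _split_roster(separable_roster, 300)
        config = fast_config(seed=0)
        mccs = []
        for perm_seed in range(4):
            rng = np.random.default_rng(perm_seed)
            shuffled = Roster(
                valid.drug_ids,
                valid.approval_years,
                rng.permutation(valid.labels),
                valid.descriptors,
                valid.descriptor_names,
            )
            mccs += [c.validation_mcc for c in fit_base_learners(train, shuffled, config)]
        assert abs(np.nanmean(mccs)) < 0.15

    def test_overlapping_ids_rejected(self, separable_roster):
        train, _ = _split_roster(separable_roster, 300)
        with pytest.raises(ValueError, match="share"):
            fit_base_learners(train, train.subset(np.arange(10)), fast_config(seed=0))

    def test_single_class_training_set_rejected(self, separable_roster):
        train, valid = _split_roster(separable_roster, 300)
        pos_only = train.subset(train.labels == 1)
        with pytest.raises(ValueError, match="single class"):
            fit_base_learners(pos_only, valid, fast_config(seed=0))


def _fake(mcc, family="knn"):
    return TrainedBaseLearner(family=family, params={}, estimator=None, validation_mcc=mcc)


class TestSelection:
    def test_vacuous_threshold_keeps_all(self):
        cands = [_fake(-0.2), _fake(0.0), _fake(0.3)]
        assert select_base_learners(cands, -1.0) == cands

    def test_strict_inequality_at_zero(self):
        cands = [_fake(-0.2), _fake(0.0), _fake(0.3)]
        kept = select_base_learners(cands, 0.0)
        assert len(kept) == 1 and kept[0].validation_mcc == 0.3

    def test_fallback_returns_single_best_flagged(self):
        cands = [_fake(-0.5), _fake(-0.1), _fake(-0.3)]
        kept = select_base_learners(cands, 0.0)
        assert len(kept) == 1
        assert kept[0].validation_mcc == -0.1 and kept[0].fallback


class TestModelLevelRepresentation:
    def test_empty_roster_zero_rows(self, separable_roster):
        train, valid = _split_roster(separable_roster, 300)
        pre = fit_preprocessor(train)
        learners = select_base_learners(
            fit_base_learners(train, valid, fast_config(seed=0), preprocessor=pre), 0.0
        )
        empty = separable_roster.subset(np.array([], dtype=int))
        mlr = build_mlr(learners, empty, pre)
        assert mlr.matrix.shape == (0, len(learners))

    def test_entries_are_probabilities(self, separable_roster):
        train, valid = _split_roster(separable_roster, 300)
        pre = fit_preprocessor(train)
        learners = fit_base_learners(train, valid, fast_config(seed=0), preprocessor=pre)
        mlr = build_mlr(learners, valid, pre)
        assert mlr.matrix.shape == (len(valid), 5)
        assert (mlr.matrix >= 0).all() and (mlr.matrix <= 1).all()

    def test_logistic_column_matches_hand_sigmoid(self):
        # fit LR alone on a toy problem and recompute its column by hand
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 2))
        y = (X[:, 0] > 0).astype(int)
        train = Roster(
            [f"t{i}" for i in range(40)], [1990] * 40, y, X, ["d0", "d1"]
        )
        probe = Roster(
            ["p0", "p1", "p2"], [1991] * 3, [0, 1, 0],
            [[0.5, -0.2], [-1.0, 0.3], [2.0, 0.0]], ["d0", "d1"],
        )
        cfg = fast_config(seed=0, algorithm_families=("logistic_regression",))
        pre = fit_preprocessor(train)
        (lrn,) = fit_base_learners(train, probe, cfg, preprocessor=pre)
        mlr = build_mlr([lrn], probe, pre)
        est = lrn.estimator
        z = pre.transform(probe) @ est.coef_.ravel() + est.intercept_[0]
        assert mlr.matrix[:, 0] == pytest.approx(1 / (1 + np.exp(-z)), abs=1e-12)


class TestMetaNetwork:
    def _perfect_mlr(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        X = y.reshape(-1, 1).astype(float)  # the single column equals the label
        return X, y

    def test_perfectly_informative_feature_learned(self):
        X, y = self._perfect_mlr()
        Xv, yv = self._perfect_mlr(n=60, seed=1)
        net = fit_meta_network(X, y, Xv, yv, MetaConfig(max_epochs=50, patience=50), seed=0)
        pred = (net.predict_proba(Xv) >= 0.5).astype(int)
        mcc = scalar_metrics(confusion_counts(yv, pred))["mcc"]
        assert mcc >= 0.95

    def test_same_seed_identical_predictions(self):
        X, y = self._perfect_mlr()
        Xv, yv = self._perfect_mlr(n=60, seed=1)
        cfg = MetaConfig(max_epochs=20, patience=20)
        p1 = fit_meta_network(X, y, Xv, yv, cfg, seed=5).predict_proba(Xv)
        p2 = fit_meta_network(X, y, Xv, yv, cfg, seed=5).predict_proba(Xv)
        assert (p1 == p2).all()

    def test_seed_stability_on_noisy_data(self):
        rng = np.random.default_rng(3)
        n = 300
        y = rng.integers(0, 2, n)
        X = y.reshape(-1, 1) * 0.6 + rng.standard_normal((n, 3)) * 0.5
        Xv, yv = X[200:], y[200:]
        X, y = X[:200], y[:200]
        cfg = MetaConfig(max_epochs=40, patience=40)
        mccs = []
        for seed in (0, 1):
            net = fit_meta_network(X, y, Xv, yv, cfg, seed=seed)
            pred = (net.predict_proba(Xv) >= 0.5).astype(int)
            mccs.append(scalar_metrics(confusion_counts(yv, pred))["mcc"])
        assert abs(mccs[0] - mccs[1]) <= 0.2

    def test_width_mismatch_rejected(self):
        X, y = self._perfect_mlr()
        with pytest.raises(ValueError, match="width"):
            fit_meta_network(X, y, np.zeros((10, 2)), np.arange(10) % 2,
                             MetaConfig(), seed=0)


class TestFullStack:
    def test_separable_dev_pool_high_internal_mcc(self, separable_roster):
        model = fit_deepdili(separable_roster, tiny_ensemble_config(seed=1))
        assert model.internal_validation_mcc > 0.8

    def test_single_class_pool_rejected(self, separable_roster):
        pool = separable_roster.subset(separable_roster.labels == 1)
        with pytest.raises(ValueError, match="single class"):
            fit_deepdili(pool, tiny_ensemble_config(seed=1))

    def test_determinism_and_serialization_roundtrip(self, tmp_path, separable_roster):
        probe = separable_roster.subset(np.arange(0, 400, 7))
        dev = separable_roster.subset(np.setdiff1d(np.arange(400), np.arange(0, 400, 7)))
        cfg = tiny_ensemble_config(seed=9)
        m1 = fit_deepdili(dev, cfg)
        m2 = fit_deepdili(dev, cfg)
        s1, l1 = m1.predict(probe)
        s2, _ = m2.predict(probe)
        assert (s1 == s2).all()  # byte-identical refit
        path = tmp_path / "model.joblib"
        save_model(m1, path)
        s3, l3 = load_model(path).predict(probe)
        assert (s1 == s3).all() and (l1 == l3).all()

    def test_predict_empty_and_score_range(self, separable_roster):
        model = fit_deepdili(separable_roster, tiny_ensemble_config(seed=1))
        empty = separable_roster.subset(np.array([], dtype=int))
        scores, labels = model.predict(empty)
        assert scores.size == 0 and labels.size == 0
        scores, _ = model.predict(separable_roster)
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_raising_threshold_never_adds_positives(self, separable_roster):
        model = fit_deepdili(separable_roster, tiny_ensemble_config(seed=1))
        counts = []
        for thr in (0.2, 0.4, 0.5, 0.6, 0.8):
            model.decision_threshold = thr
            _, labels = model.predict(separable_roster)
            counts.append(int(labels.sum()))
        assert counts == sorted(counts, reverse=True)
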