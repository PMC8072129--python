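"""Classifier training and its diagnostics: AUC, curves, importances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from fldscreen import (ClassifierConfig, auc, cross_val_auc,
                       false_negative_summary, feature_importance,
                       incremental_feature_curve, learning_curve,
                       train_classifier)
from fldscreen.exceptions import InputError, TrainingError

from oracles import auc_pairs


def toy_cohort(n=400, seed=0, n_noise=9):
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.35).astype(float)
    t = pd.DataFrame({"sex": rng.integers(0, 2, n),
                      "age": rng.integers(20, 80, n).astype(float),
                      "fld": y,
                      "signal": rng.standard_normal(n) + 2.0 * y})
    for j in range(n_noise):
        t[f"noise{j}"] = rng.standard_normal(n)
    return t


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pair_enumeration_example(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        y = [0, 0, 1, 1]
        assert auc(scores, y) == pytest.approx(auc_pairs(scores, y), abs=1e-12)

    def test_oracle_agreement_with_ties(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(4, 40))
            s = rng.integers(0, 6, n).astype(float) / 5
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            assert auc(s, y) == pytest.approx(auc_pairs(s, y), abs=1e-12)
            assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)
            # scores are spaced >= 0.2 apart, so exp is strictly monotone here
            assert auc(np.exp(s), y) == pytest.approx(auc(s, y), abs=1e-12)

    @given(st.lists(st.tuples(st.floats(-5, 5), st.integers(0, 1)),
                    min_size=4, max_size=40))
    def test_monotone_transform_invariance_and_negation(self, pairs):
        s = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if y.sum() in (0, len(y)):
            return
        base = auc(s, y)
        # power-of-two scaling is exact in floats, hence strictly monotone
        assert auc(4.0 * s, y) == pytest.approx(base, abs=1e-12)
        assert auc(-s, y) == pytest.approx(1.0 - base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            auc([0.1, 0.9], [1, 1])


class TestTraining:
    def test_separable_data_trains_to_auc_one(self):
        t = toy_cohort(200, seed=1, n_noise=0)
        t["signal"] = t["fld"] * 10.0  # perfectly separable
        handle = train_classifier(t)
        assert auc(handle.scores(t), t["fld"].astype(int)) == 1.0

    def test_permuted_labels_give_null_auc(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            t = toy_cohort(2000, seed=seed)
            t["fld"] = rng.permutation(t["fld"].to_numpy())
            train, test = t.iloc[:1400], t.iloc[1400:]
            handle = train_classifier(train, ClassifierConfig(seed=seed))
            aucs.append(auc(handle.scores(test), test["fld"].astype(int)))
        assert 0.45 <= np.mean(aucs) <= 0.55

    def test_seeded_determinism(self):
        t = toy_cohort(300, seed=2)
        s1 = train_classifier(t, ClassifierConfig(seed=5)).scores(t)
        s2 = train_classifier(t, ClassifierConfig(seed=5)).scores(t)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self):
        t = toy_cohort(100, seed=3)
        t["fld"] = 0.0
        with pytest.raises(TrainingError):
            train_classifier(t)

    def test_default_hyperparameters_fixed(self):
        cfg = ClassifierConfig()
        assert (cfg.max_depth, cfg.learning_rate, cfg.n_estimators,
                cfg.scale_pos_weight, cfg.min_child_weight, cfg.gamma,
                cfg.reg_alpha) == (3, 0.07, 150, 2.0, 6.0, 0.2, 0.1)


class TestLearningCurve:
    def test_single_point_equals_direct_fit(self):
        t = toy_cohort(300, seed=4)
        train, test = t.iloc[:200], t.iloc[200:]
        curve = learning_curve(train, test, ClassifierConfig(), [1])
        direct = train_classifier(train, ClassifierConfig().replace_estimators(1))
        assert curve["train_auc"].iloc[0] == pytest.approx(
            auc(direct.scores(train), train["fld"].astype(int)))

    def test_train_auc_weakly_increasing(self):
        t = toy_cohort(400, seed=5)
        train, test = t.iloc[:300], t.iloc[300:]
        curve = learning_curve(train, test, ClassifierConfig(), [1, 10, 100])
        diffs = np.diff(curve["train_auc"].to_numpy())
        assert np.all(diffs >= -1e-9)

    def test_bad_grid_rejected(self):
        t = toy_cohort(100, seed=6)
        with pytest.raises(InputError):
            learning_curve(t, t, ClassifierConfig(), [10, 5])


class TestImportance:
    def test_planted_feature_ranked_first(self):
        hits = 0
        for seed in range(10):
            handle = train_classifier(toy_cohort(800, seed=seed),
                                      ClassifierConfig(seed=seed))
            ranked = feature_importance(handle)
            hits += ranked["feature"].iloc[0] == "signal"
        assert hits >= 9

    def test_counts_sum_to_total_splits(self):
        handle = train_classifier(toy_cohort(300, seed=7))
        ranked = feature_importance(handle)
        trees = handle.model.get_booster().trees_to_dataframe()
        total_splits = (trees["Feature"] != "Leaf").sum()
        assert ranked["split_count"].sum() == total_splits

    def test_ordering_is_stable_sort_by_count_then_name(self):
        handle = train_classifier(toy_cohort(300, seed=8))
        ranked = feature_importance(handle)
        resorted = ranked.sort_values(["split_count", "feature"],
                                      ascending=[False, True],
                                      kind="stable").reset_index(drop=True)
        pd.testing.assert_frame_equal(ranked, resorted)


class TestIncrementalCurve:
    def test_full_feature_set_matches_full_model(self):
        t = toy_cohort(400, seed=9)
        train, test = t.iloc[:300], t.iloc[300:]
        handle = train_classifier(train)
        ranked = feature_importance(handle)["feature"].tolist()
        curve = incremental_feature_curve(train, test, ClassifierConfig(),
                                          ranked, len(ranked))
        # the m = all model uses the same features, order aside
        full = auc(train_classifier(train, columns=ranked).scores(test),
                   test["fld"].astype(int))
        assert curve["test_auc"].iloc[-1] == pytest.approx(full)

    def test_single_planted_feature_beats_null(self):
        t = toy_cohort(1200, seed=10)
        train, test = t.iloc[:800], t.iloc[800:]
        curve = incremental_feature_curve(train, test, ClassifierConfig(),
                                          ["signal"], 1)
        assert curve["test_auc"].iloc[0] > 0.7


class TestFalseNegatives:
    def test_threshold_zero_no_false_negatives(self):
        t = toy_cohort(200, seed=11)
        out = false_negative_summary(t, np.full(len(t), 0.5), threshold=0.0)
        assert (out["n_false_negatives"] == 0).all()

    def test_threshold_one_summary_equals_positive_class(self):
        t = toy_cohort(200, seed=12)
        out = false_negative_summary(t, np.full(len(t), 0.5), threshold=1.0)
        assert (out["n_false_negatives"] == out["n_positives"]).all()
        np.testing.assert_allclose(out["mean_false_negative"],
                                   out["mean_positive"])

    def test_missed_cases_look_more_normal(self):
        t = toy_cohort(1500, seed=13)
        train, test = t.iloc[:1000], t.iloc[1000:]
        handle = train_classifier(train)
        out = false_negative_summary(test, handle.scores(test))
        row = out.set_index("feature").loc["signal"]
        assert row["mean_false_negative"] < row["mean_positive"]


def test_cross_val_auc_three_folds():
    out = cross_val_auc(toy_cohort(600, seed=14))
    assert len(out) == 3
    assert out["test_auc"].between(0.5, 1.0).all()
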