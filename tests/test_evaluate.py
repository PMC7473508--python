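import numpy as np
import pandas as pd
import pytest

from ringtex.evaluate import (CLASSIFIERS, ClassifierSpec, confusion_metrics,
                              cross_validate, evaluate_all, roc_auc,
                              stratified_kfold)
from ringtex.phantom import synthetic_feature_table

from oracles import auc_mann_whitney


def blobs_table(n_per_class=(20, 20), n_features=4, shift=5.0, seed=0):
    """Two well-separated Gaussian blobs."""
    table, _ = synthetic_feature_table(n_per_class=n_per_class,
                                       n_features=n_features,
                                       n_informative=n_features,
                                       shift_sd=shift, seed=seed)
    return table


class TestStratifiedKFold:
    def test_cohort_30_37_fold_composition(self):
        labels = np.array(["inflammatory"] * 30 + ["tumor"] * 37)
        folds = stratified_kfold(labels, k=10, seed=0)
        for f in range(10):
            members = labels[folds == f]
            assert len(members) in (6, 7)
            assert np.sum(members == "inflammatory") == 3
            assert np.sum(members == "tumor") in (3, 4)

    def test_leave_one_out_when_k_equals_n(self):
        labels = np.array(["a", "b"] * 5)
        folds = stratified_kfold(labels, k=5, seed=1)
        assert len(np.unique(folds)) == 5

    def test_deterministic_under_seed(self):
        labels = np.array(["a"] * 15 + ["b"] * 15)
        np.testing.assert_array_equal(stratified_kfold(labels, seed=4),
                                      stratified_kfold(labels, seed=4))

    def test_k_reduced_with_warning(self):
        labels = np.array(["a"] * 3 + ["b"] * 20)
        with pytest.warns(UserWarning, match="reducing folds"):
            folds = stratified_kfold(labels, k=10, seed=0)
        assert len(np.unique(folds)) == 3

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(np.array(["a"] * 10), k=2, seed=0)


class TestCrossValidate:
    @pytest.mark.parametrize("method", CLASSIFIERS)
    def test_separable_blobs_perfect_metrics(self, method):
        table = blobs_table()
        folds = stratified_kfold(table["label"].to_numpy(), k=10, seed=0)
        cv = cross_validate(table, ClassifierSpec(method=method, seed=0),
                            folds)
        assert len(cv) == len(table)
        metrics = confusion_metrics(cv)
        _, auc = roc_auc(cv)
        assert metrics["CA"] == 1.0
        assert auc == 1.0

    def test_every_lesion_predicted_once(self):
        table = blobs_table(shift=1.0, seed=3)
        folds = stratified_kfold(table["label"].to_numpy(), k=10, seed=0)
        cv = cross_validate(table, ClassifierSpec(method="knn"), folds)
        assert sorted(cv["lesion_id"]) == sorted(table["lesion_id"])

    def test_permuted_labels_null_auc(self):
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            table = blobs_table(n_per_class=(20, 20), seed=seed)
            table["label"] = rng.permutation(table["label"].to_numpy())
            folds = stratified_kfold(table["label"].to_numpy(), k=10,
                                     seed=seed)
            cv = cross_validate(table, ClassifierSpec(method="knn"), folds)
            aucs.append(roc_auc(cv)[1])
        assert abs(np.mean(aucs) - 0.5) < 0.1

    def test_scores_in_unit_interval(self):
        table = blobs_table(shift=1.0, seed=5)
        folds = stratified_kfold(table["label"].to_numpy(), k=5, seed=0)
        for method in CLASSIFIERS:
            cv = cross_validate(table, ClassifierSpec(method=method), folds)
            assert cv["score"].between(0, 1).all()


class TestConfusionMetrics:
    def test_stated_confusion_matrix_arithmetic(self):
        # TP=31, FN=3, FP=6, TN=27 on 67 predictions
        rows = ([("tumor", "tumor")] * 31 + [("tumor", "inflammatory")] * 3
                + [("inflammatory", "tumor")] * 6
                + [("inflammatory", "inflammatory")] * 27)
        cv = pd.DataFrame([{"y_true": t, "y_pred": p, "score": 0.5}
                           for t, p in rows])
        m = confusion_metrics(cv)
        assert m["recall"] == pytest.approx(31 / 34)
        assert m["precision"] == pytest.approx(31 / 37)
        assert m["CA"] == pytest.approx(58 / 67)

    def test_all_correct(self):
        cv = pd.DataFrame({"y_true": ["tumor", "inflammatory"],
                           "y_pred": ["tumor", "inflammatory"],
                           "score": [0.9, 0.1]})
        m = confusion_metrics(cv)
        assert m == {"CA": 1.0, "F1": 1.0, "precision": 1.0, "recall": 1.0}

    def test_matches_count_oracle_on_random_predictions(self, rng):
        classes = np.array(["inflammatory", "tumor"])
        yt = rng.choice(classes, 200)
        yp = rng.choice(classes, 200)
        cv = pd.DataFrame({"y_true": yt, "y_pred": yp, "score": 0.5})
        m = confusion_metrics(cv)
        tp = np.sum((yt == "tumor") & (yp == "tumor"))
        fp = np.sum((yt != "tumor") & (yp == "tumor"))
        fn = np.sum((yt == "tumor") & (yp != "tumor"))
        assert m["CA"] == np.mean(yt == yp)
        assert m["precision"] == pytest.approx(tp / (tp + fp))
        assert m["recall"] == pytest.approx(tp / (tp + fn))

    def test_zero_denominator_warns_and_returns_zero(self):
        cv = pd.DataFrame({"y_true": ["inflammatory", "inflammatory"],
                           "y_pred": ["inflammatory", "inflammatory"],
                           "score": [0.1, 0.2]})
        with pytest.warns(UserWarning):
            m = confusion_metrics(cv)
        assert m["precision"] == 0.0 and m["recall"] == 0.0


class TestROC:
    def test_perfectly_ordered_scores(self):
        cv = pd.DataFrame({"y_true": ["tumor"] * 5 + ["inflammatory"] * 5,
                           "y_pred": ["tumor"] * 10,
                           "score": np.r_[np.linspace(0.6, 1, 5),
                                          np.linspace(0, 0.4, 5)]})
        points, auc = roc_auc(cv)
        assert auc == 1.0
        assert points["FPR"].iloc[0] == 0 and points["TPR"].iloc[-1] == 1
        assert points["FPR"].is_monotonic_increasing
        assert points["TPR"].is_monotonic_increasing

    def test_all_tied_scores_give_half(self):
        cv = pd.DataFrame({"y_true": ["tumor"] * 4 + ["inflammatory"] * 4,
                           "y_pred": ["tumor"] * 8, "score": 0.5})
        _, auc = roc_auc(cv)
        assert auc == 0.5

    def test_trapezoid_equals_mann_whitney(self, rng):
        for _ in range(20):
            yt = rng.choice(["inflammatory", "tumor"], 20)
            if len(set(yt)) < 2:
                continue
            scores = np.round(rng.uniform(0, 1, 20), 1)  # force ties
            cv = pd.DataFrame({"y_true": yt, "y_pred": yt, "score": scores})
            _, auc = roc_auc(cv)
            want = auc_mann_whitney(yt, scores, "tumor")
            assert auc == pytest.approx(want, abs=1e-12)

    def test_single_class_rejected(self):
        cv = pd.DataFrame({"y_true": ["tumor"] * 3, "y_pred": ["tumor"] * 3,
                           "score": [0.1, 0.5, 0.9]})
        with pytest.raises(ValueError):
            roc_auc(cv)


class TestEvaluateAll:
    def test_report_shape_three_classifiers_two_modes(self):
        table = blobs_table(n_per_class=(15, 15), n_features=8, seed=6)
        report = evaluate_all(table, seed=0)
        assert len(report) == 6
        assert set(report["classifier"]) == set(CLASSIFIERS)
        assert set(report["feature_mode"]) == {"all", "top5"}
        for col in ("AUC", "CA", "F1", "precision", "recall"):
            assert report[col].between(0, 1).all()
        assert len(report.attrs["roc"]) == 6

    def test_anti_leakage_on_pure_noise(self):
        """Fold-internal selection stays near chance on pure-noise features;
        global (leaky) selection biases the AUC upward."""
        fair_aucs, leaky_aucs = [], []
        for seed in range(8):
            table, _ = synthetic_feature_table(
                n_per_class=(20, 20), n_features=40, n_informative=0,
                shift_sd=0.0, seed=seed)
            for leaky, sink in ((False, fair_aucs), (True, leaky_aucs)):
                report = evaluate_all(table, seed=seed, methods=("knn",),
                                      feature_modes=("top5",), select_k=5,
                                      leaky_top5=leaky)
                sink.append(report["AUC"].iloc[0])
        assert abs(np.mean(fair_aucs) - 0.5) < 0.12
        assert np.mean(leaky_aucs) > np.mean(fair_aucs)

    def test_holdout_protocol_evaluates_quarter(self):
        table = blobs_table(n_per_class=(20, 20), n_features=6, seed=9)
        report = evaluate_all(table, seed=0, methods=("knn",),
                              feature_modes=("all",), protocol="holdout")
        assert report["CA"].iloc[0] == 1.0  # separable blobs
        roc = report.attrs["roc"][("knn", "all")]
        assert len(roc) >= 2
        with pytest.raises(ValueError, match="protocol"):
            evaluate_all(table, protocol="bogus")

    def test_deterministic_under_seed(self):
        table = blobs_table(n_per_class=(12, 12), n_features=6, shift=1.0,
                            seed=7)
        r1 = evaluate_all(table, seed=3, methods=("random_forest",))
        r2 = evaluate_all(table, seed=3, methods=("random_forest",))
        pd.testing.assert_frame_equal(r1, r2)
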