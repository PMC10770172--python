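"""Classifiers, metrics, ROC/AUC, cross-validation, and the flag ablation."""

import numpy as np
import pandas as pd
import pytest

from lesionfuse.classify import (
    CLASSIFIER_NAMES,
    ClassifierConfig,
    count_dense_params,
    cross_validate,
    evaluate_metrics,
    flag_ablation,
    make_classifier,
    roc_auc,
    split_train_test,
)
from lesionfuse.errors import (
    InvalidInputError,
    UndefinedAucError,
    UnsupportedClassifierError,
)
from lesionfuse.fusion import BN_COLS
from lesionfuse.synthetic import generate_dataset


class TestMakeClassifier:
    def test_svm_sigmoid_kernel(self):
        model = make_classifier(ClassifierConfig(name="svm"))
        assert model.kernel == "sigmoid"

    def test_bagging_ten_tree_estimators(self):
        model = make_classifier(ClassifierConfig(name="bagging"))
        assert model.n_estimators == 10

    def test_gradient_boosting_twenty_estimators(self):
        model = make_classifier(ClassifierConfig(name="gradient_boosting"))
        assert model.n_estimators == 20 and model.learning_rate == 0.1

    def test_xgboost_hundred_estimators_with_eta(self):
        model = make_classifier(ClassifierConfig(name="xgboost"))
        assert model.n_estimators == 100 and model.learning_rate == 0.1

    def test_unknown_name_rejected(self):
        with pytest.raises(UnsupportedClassifierError):
            make_classifier(ClassifierConfig(name="fancy_net"))

    def test_all_seven_fit_predict(self):
        rng = np.random.default_rng(0)
        x = rng.random((40, 5))
        y = (x[:, 0] > 0.5).astype(int)
        for name in CLASSIFIER_NAMES:
            model = make_classifier(ClassifierConfig(name=name, seed=0))
            model.fit(x, y)
            assert model.predict_proba(x).shape == (40, 2)


class TestCountDenseParams:
    @pytest.mark.parametrize("inw,outw,expected", [
        (784, 512, 401920),
        (512, 256, 131328),
        (256, 2, 514),
        (1, 1, 2),
    ])
    def test_values(self, inw, outw, expected):
        assert count_dense_params(inw, outw) == expected


class TestSplit:
    def test_70_30_counts(self):
        samples = generate_dataset(100, seed=0, hairy_fraction=0, image_size=(64, 64))
        train, test = split_train_test(samples, 0.7, seed=1)
        assert len(train) == 70 and len(test) == 30
        assert not {s.sample_id for s in train} & {s.sample_id for s in test}

    def test_reproducible(self):
        samples = generate_dataset(40, seed=1, hairy_fraction=0, image_size=(64, 64))
        a = split_train_test(samples, 0.7, seed=5)
        b = split_train_test(samples, 0.7, seed=5)
        assert [s.sample_id for s in a[0]] == [s.sample_id for s in b[0]]

    def test_stratification_preserved(self):
        samples = generate_dataset(40, malignant_fraction=0.5, seed=2,
                                   hairy_fraction=0, image_size=(64, 64))
        train, test = split_train_test(samples, 0.7, seed=0)
        assert abs(sum(s.label for s in train) - 14) <= 1
        assert abs(sum(s.label for s in test) - 6) <= 1

    def test_bad_fraction_rejected(self):
        samples = generate_dataset(10, seed=3, hairy_fraction=0, image_size=(64, 64))
        with pytest.raises(InvalidInputError):
            split_train_test(samples, 1.2)


class TestEvaluateMetrics:
    def test_worked_confusion(self):
        # TP=88, FN=12, TN=98, FP=2
        truth = [1] * 100 + [0] * 100
        pred = [1] * 88 + [0] * 12 + [0] * 98 + [1] * 2
        r = evaluate_metrics(pred, truth)
        assert r.sensitivity == pytest.approx(88.0)
        assert r.specificity == pytest.approx(98.0)
        assert r.accuracy == pytest.approx(93.0)
        assert r.precision == pytest.approx(100 * 88 / 90, abs=0.01)  # ~97.78

    def test_all_correct_hundred_percent(self):
        r = evaluate_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert r.accuracy == r.precision == r.sensitivity == r.specificity == 100.0

    def test_no_positive_predictions_flagged_not_zero(self):
        r = evaluate_metrics([0, 0, 0], [0, 1, 0])
        assert r.precision is None and "Pre" in r.undefined

    def test_identity_with_confusion_counts(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, 50)
        truth = rng.integers(0, 2, 50)
        r = evaluate_metrics(pred, truth)
        assert r.n == 50
        assert r.accuracy == pytest.approx(
            100 * (r.true_malignant + r.true_benign) / r.n)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            evaluate_metrics([], [])


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_identical_scores_half(self):
        _, auc = roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_matches_mann_whitney_pair_counting(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            scores = np.round(rng.random(40), 2)  # ties likely
            truth = rng.integers(0, 2, 40)
            if truth.min() == truth.max():
                continue
            _, auc = roc_auc(scores, truth)
            pos, neg = scores[truth == 1], scores[truth == 0]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc == pytest.approx(oracle, abs=1e-12)

    def test_sign_reversal_flips_auc(self):
        rng = np.random.default_rng(8)
        scores = rng.random(30)
        truth = rng.integers(0, 2, 30)
        _, auc = roc_auc(scores, truth)
        _, rev = roc_auc(-scores, truth)
        assert auc + rev == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAucError):
            roc_auc([0.2, 0.8], [1, 1])


class TestCrossValidate:
    def make_xy(self, n=30):
        rng = np.random.default_rng(1)
        x = rng.random((n, 4))
        y = (x[:, 0] > 0.5).astype(int)
        return x, y

    def test_folds_partition_all_samples(self):
        x, y = self.make_xy()
        reports, mean = cross_validate(ClassifierConfig("decision_tree"), x, y, k=5)
        assert sum(r.n for r in reports) == len(y)

    def test_leave_one_out_fold_sizes(self):
        x, y = self.make_xy(10)
        reports, _ = cross_validate(ClassifierConfig("decision_tree"), x, y, k=10)
        assert len(reports) == 10 and all(r.n == 1 for r in reports)

    def test_constant_prediction_accuracy_is_majority_fraction(self):
        # constant features force the tree to predict the training majority
        n = 30
        x = np.zeros((n, 3))
        y = np.array([1] * 20 + [0] * 10)
        _, mean = cross_validate(ClassifierConfig("decision_tree"), x, y, k=5, seed=0)
        overall = mean["overall"]["confusion"]
        pred_pos = overall["True_Malignant"] + overall["False_Malignant"]
        assert pred_pos == n  # always predicts the majority class
        assert mean["overall"]["Acc"] == pytest.approx(100 * 20 / 30)

    def test_invalid_k_rejected(self):
        x, y = self.make_xy(10)
        with pytest.raises(InvalidInputError):
            cross_validate(ClassifierConfig("decision_tree"), x, y, k=11)


class TestFlagAblation:
    def make_table(self, n=120, flag_signal=True, seed=0):
        """Bottleneck columns are pure noise; flags carry the label when
        flag_signal, otherwise they are noise too."""
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        bn = rng.normal(size=(n, 64))
        df = pd.DataFrame(bn, columns=BN_COLS)
        for col in ("A", "B", "C", "D", "E"):
            df[col] = rng.normal(size=n)
        if flag_signal:
            df["S_Flag1"] = y * 0.4 + rng.normal(0, 0.02, n)
        else:
            df["S_Flag1"] = rng.normal(size=n)
        df["S_Flag2"] = rng.normal(size=n)
        df["S_Flag3"] = rng.normal(size=n)
        df.insert(0, "sample_id", [f"s{i}" for i in range(n)])
        df["label"] = y
        return df

    def test_flag_only_signal_improves_specificity(self):
        table = self.make_table(flag_signal=True)
        result = flag_ablation(table, seed=0)
        assert (result["delta"] > 0).sum() >= 4

    def test_noise_flags_small_delta(self):
        deltas = []
        for seed in range(5):
            result = flag_ablation(self.make_table(flag_signal=False, seed=seed),
                                   seed=seed)
            deltas.extend(result["delta"].dropna().tolist())
        assert abs(np.mean(deltas)) <= 5.0

    def test_constant_flags_zero_delta_for_deterministic_models(self):
        # constant flag columns cannot change the learned function for models
        # whose fit ignores uninformative features outright (bagging/boosting
        # draw from a feature-count-dependent RNG stream, so they are exempt)
        table = self.make_table(flag_signal=False)
        for col in ("S_Flag1", "S_Flag2", "S_Flag3"):
            table[col] = 1.0
        configs = [ClassifierConfig(n, seed=0) for n in ("decision_tree", "xgboost")]
        result = flag_ablation(table, classifiers=configs, seed=0)
        assert (result["delta"].abs() < 1e-9).all()

    def test_missing_flag_columns_rejected(self):
        table = self.make_table().drop(columns=["S_Flag2"])
        with pytest.raises(InvalidInputError):
            flag_ablation(table)
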