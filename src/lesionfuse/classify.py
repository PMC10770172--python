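"""The seven tabular classifiers, evaluation metrics, ROC/AUC, k-fold
cross-validation, and the with/without-'F' specificity ablation.

The malignant class is positive throughout.  With confusion counts
True_Malignant (TM), True_Benign (TB), False_Malignant (FM, benign predicted
malignant) and False_Benign (FB):

    Acc  = (TM + TB) / N
    Pre  = TM / (TM + FM)
    Sens = TM / (TM + FB)          (recall on melanoma)
    Spec = TB / (TB + FM)          (recall on benign)

all reported as percentages; zero denominators are flagged as undefined
(``None``) rather than coerced to zero.  AUC comes from a threshold sweep
over the unique scores with trapezoidal integration, which equals the
Mann-Whitney pair-counting statistic with ties counted 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import BaggingClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .errors import InvalidInputError, UndefinedAucError, UnsupportedClassifierError
from .fusion import FLAG_COLS

CLASSIFIER_NAMES = (
    "mlp", "gradient_boosting", "bagging", "xgboost",
    "decision_tree", "svm", "logistic_regression",
)


@dataclass(frozen=True)
class ClassifierConfig:
    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0


def make_classifier(config: ClassifierConfig):
    """Seeded estimator with the stated default hyperparameters.

    Defaults: gradient boosting with 20 estimators / learning rate 0.1 /
    deviance (log) loss; bagging over 10 decision trees; XGBoost with 100
    estimators and eta 0.1; sigmoid-kernel SVM; Gini decision tree; MLP with
    the 512-256 hidden stack (the "prose" preset swaps in three 64-unit
    hidden layers).
    """
    hp = dict(config.hyperparameters)
    seed = config.seed
    if config.name == "mlp":
        hidden = (64, 64, 64) if hp.pop("preset", None) == "prose" else (512, 256)
        return MLPClassifier(hidden_layer_sizes=hp.pop("hidden_layer_sizes", hidden),
                             activation="relu", max_iter=hp.pop("max_iter", 300),
                             random_state=seed, **hp)
    if config.name == "gradient_boosting":
        return GradientBoostingClassifier(n_estimators=hp.pop("n_estimators", 20),
                                          learning_rate=hp.pop("learning_rate", 0.1),
                                          loss="log_loss", random_state=seed, **hp)
    if config.name == "bagging":
        return BaggingClassifier(estimator=DecisionTreeClassifier(random_state=seed),
                                 n_estimators=hp.pop("n_estimators", 10),
                                 random_state=seed, **hp)
    if config.name == "xgboost":
        return XGBClassifier(n_estimators=hp.pop("n_estimators", 100),
                             learning_rate=hp.pop("learning_rate", 0.1),
                             random_state=seed, eval_metric="logloss",
                             verbosity=0, **hp)
    if config.name == "decision_tree":
        return DecisionTreeClassifier(criterion="gini", random_state=seed, **hp)
    if config.name == "svm":
        return SVC(kernel="sigmoid", probability=True, random_state=seed, **hp)
    if config.name == "logistic_regression":
        return LogisticRegression(max_iter=hp.pop("max_iter", 1000), **hp)
    raise UnsupportedClassifierError(f"unknown classifier {config.name!r}")


def count_dense_params(in_width: int, out_width: int) -> int:
    """Weights + biases of one fully connected layer: in*out + out."""
    if in_width < 1 or out_width < 1:
        raise InvalidInputError("layer widths must be >= 1")
    return in_width * out_width + out_width


def split_train_test(samples, train_fraction: float = 0.7, seed: int = 0):
    """Stratified, disjoint, exhaustive 70:30 (default) split of samples."""
    if not 0 < train_fraction < 1:
        raise InvalidInputError(f"train_fraction {train_fraction} outside (0,1)")
    samples = list(samples)
    if len(samples) < 2:
        raise InvalidInputError("need at least 2 samples to split")
    labels = [s.label for s in samples]
    if len(set(labels)) < 2:
        raise InvalidInputError("both classes must be present")
    idx_train, idx_test = train_test_split(
        np.arange(len(samples)), train_size=train_fraction,
        stratify=labels, random_state=seed,
    )
    return [samples[i] for i in idx_train], [samples[i] for i in idx_test]


@dataclass
class EvaluationReport:
    true_malignant: int
    true_benign: int
    false_malignant: int
    false_benign: int
    accuracy: float | None  # percent
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    undefined: tuple = ()  # names of metrics with zero denominators
    auc: float | None = None
    roc_points: np.ndarray | None = None

    @property
    def n(self):
        return self.true_malignant + self.true_benign + self.false_malignant + self.false_benign

    def as_dict(self):
        return {
            "confusion": {"True_Malignant": self.true_malignant,
                          "True_Benign": self.true_benign,
                          "False_Malignant": self.false_malignant,
                          "False_Benign": self.false_benign},
            "Acc": self.accuracy, "Pre": self.precision,
            "Sens": self.sensitivity, "Spec": self.specificity,
            "AUC": self.auc, "undefined": list(self.undefined),
        }


def evaluate_metrics(predictions, truth) -> EvaluationReport:
    """Confusion counts and percentage metrics (malignant = positive)."""
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(truth, dtype=int)
    if pred.shape != y.shape or pred.size == 0:
        raise InvalidInputError("predictions and truth must be equal-length, non-empty")
    tm = int(np.sum((pred == 1) & (y == 1)))
    tb = int(np.sum((pred == 0) & (y == 0)))
    fm = int(np.sum((pred == 1) & (y == 0)))
    fb = int(np.sum((pred == 0) & (y == 1)))
    undefined = []

    def pct(num, den, name):
        if den == 0:
            undefined.append(name)
            return None
        return 100.0 * num / den

    report = EvaluationReport(
        true_malignant=tm, true_benign=tb, false_malignant=fm, false_benign=fb,
        accuracy=pct(tm + tb, tm + tb + fm + fb, "Acc"),
        precision=pct(tm, tm + fm, "Pre"),
        sensitivity=pct(tm, tm + fb, "Sens"),
        specificity=pct(tb, tb + fm, "Spec"),
    )
    report.undefined = tuple(undefined)
    return report


def roc_auc(scores, truth):
    """(roc_points, AUC) via a threshold sweep at every unique score.

    Each threshold t contributes (FPR, TPR) for the rule score >= t; with the
    endpoints (0,0) and (1,1) and trapezoidal integration this reproduces the
    Mann-Whitney statistic P(score_pos > score_neg) + P(equal)/2 exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=int)
    if s.shape != y.shape or s.size == 0:
        raise InvalidInputError("scores and truth must be equal-length, non-empty")
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAucError("AUC needs both classes in the truth vector")
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [len(s_sorted) - 1]])
    tps = np.cumsum(y_sorted == 1)[cut]
    fps = np.cumsum(y_sorted == 0)[cut]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.stack([fpr, tpr], axis=1), auc


def cross_validate(config: ClassifierConfig, features, labels, k: int, seed: int = 0):
    """Stratified k-fold (plain shuffled k-fold when k exceeds the minority
    class count, e.g. leave-one-out); every sample is tested exactly once.

    Returns (per-fold EvaluationReports, mean metric dict).
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if k < 2 or k > len(y):
        raise InvalidInputError(f"k={k} invalid for n={len(y)}")
    min_class = min(np.bincount(y, minlength=2))
    splitter = (StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
                if k <= min_class else KFold(n_splits=k, shuffle=True, random_state=seed))
    reports, fold_preds = [], np.empty(len(y), dtype=int)
    base = make_classifier(config)
    for train_idx, test_idx in splitter.split(x, y):
        model = clone(base)
        model.fit(x[train_idx], y[train_idx])
        pred = model.predict(x[test_idx])
        fold_preds[test_idx] = pred
        reports.append(evaluate_metrics(pred, y[test_idx]))
    mean = {}
    for key in ("accuracy", "precision", "sensitivity", "specificity"):
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        mean[key] = float(np.mean(vals)) if vals else None
    mean["overall"] = evaluate_metrics(fold_preds, y).as_dict()
    return reports, mean


class ClinicalScaler:
    """Min-max scaling of the non-bottleneck columns, fit on training rows only.

    Bottleneck activations are left untouched; the clinical scores carry
    TDS-scale magnitudes that would otherwise dominate distance-based models.
    """

    def __init__(self, columns):
        self.columns = list(columns)

    def fit(self, df: pd.DataFrame):
        self.lo = df[self.columns].min(axis=0)
        span = df[self.columns].max(axis=0) - self.lo
        self.span = span.replace(0.0, 1.0)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out[self.columns] = (df[self.columns] - self.lo) / self.span
        return out


def _fit_eval_specificity(config, x_train, y_train, x_test, y_test):
    model = make_classifier(config)
    model.fit(x_train, y_train)
    return evaluate_metrics(model.predict(x_test), y_test)


def flag_ablation(table: pd.DataFrame, classifiers=None, seed: int = 0,
                  train_fraction: float = 0.7) -> pd.DataFrame:
    """Specificity with vs without the flag columns, identical split.

    ``table`` is an extended fused-feature table (must contain the S_Flag
    columns plus ``label``).  Each classifier is trained twice — once on the
    full feature set and once with the flag columns removed — and the per-
    classifier delta Spec_with - Spec_without (percentage points) is reported.
    """
    missing = [c for c in FLAG_COLS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"feature table lacks flag columns {missing}")
    if classifiers is None:
        classifiers = [ClassifierConfig(name=n, seed=seed) for n in CLASSIFIER_NAMES]
    y = table["label"].to_numpy(dtype=int)
    feat_cols = [c for c in table.columns if c not in ("sample_id", "label")]
    clinical = [c for c in feat_cols if not c.startswith("bn_")]
    idx_train, idx_test = train_test_split(np.arange(len(table)),
                                           train_size=train_fraction,
                                           stratify=y, random_state=seed)
    scaler = ClinicalScaler(clinical).fit(table.iloc[idx_train])
    scaled = scaler.transform(table)
    rows = []
    for config in classifiers:
        res = {}
        for tag, cols in (("with", feat_cols),
                          ("without", [c for c in feat_cols if c not in FLAG_COLS])):
            x = scaled[cols].to_numpy(dtype=float)
            res[tag] = _fit_eval_specificity(config, x[idx_train], y[idx_train],
                                             x[idx_test], y[idx_test])
        spec_w = res["with"].specificity
        spec_wo = res["without"].specificity
        rows.append({"classifier": config.name,
                     "spec_with": spec_w, "spec_without": spec_wo,
                     "delta": None if spec_w is None or spec_wo is None
                     else spec_w - spec_wo})
    return pd.DataFrame(rows)
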