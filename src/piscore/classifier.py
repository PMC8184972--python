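"""Training and evaluation of the interface classifier, and the PI-score.

The classifier separates native-like from non-native interfaces in the
12-feature space. The production model is a support vector machine on
standardized features; the PI-score of an interface is its signed distance
from the decision hyperplane (positive = native-like, magnitude =
confidence). Cross-validation uses repeated stratified 70/30 shuffle splits.
Alternative learners (random forest, neural network, gradient boosting) are
available for performance comparison and expose a comparable signed score.

`InterfaceClassifier` is a scikit-learn estimator (fit / predict /
decision_function, get_params/set_params, trailing-underscore fitted
attributes) and composes with sklearn model selection.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, check_X_y, check_array

from .physchem_features import FEATURE_NAMES

__all__ = [
    "LabeledDataset", "InterfaceClassifier", "ConfusionCounts",
    "confusion_metrics", "train_classifier", "pi_score",
    "binned_performance", "rank_features", "casp_agreement",
    "save_model", "load_model",
]


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels and per-row provenance (PD1/PD2/ND)."""

    X: np.ndarray                       # n x 12
    y: np.ndarray                       # 1 = native-like, 0 = non-native
    provenance: np.ndarray | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X and y shapes do not match")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("dataset contains missing/non-finite values")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance)

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        prov = self.provenance[mask] if self.provenance is not None else None
        return LabeledDataset(self.X[mask], self.y[mask], prov, self.feature_names)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["label"] = self.y
        if self.provenance is not None:
            df["provenance"] = self.provenance
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LabeledDataset":
        missing = [c for c in FEATURE_NAMES if c not in df.columns]
        if missing or "label" not in df.columns:
            raise ValueError(f"dataset CSV lacks columns: {missing + (['label'] if 'label' not in df.columns else [])}")
        prov = df["provenance"].to_numpy() if "provenance" in df.columns else None
        return cls(df[list(FEATURE_NAMES)].to_numpy(float),
                   df["label"].to_numpy(int), prov)


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for v in (self.tp, self.tn, self.fp, self.fn):
            if v < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else float("nan")


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """The seven performance metrics from a confusion table.

    TPR = TP/(TP+FN); FPR = FP/(TN+FP); Precision = TP/(TP+FP);
    Accuracy = (TP+TN)/total; F1 = 2 Precision TPR / (Precision + TPR);
    Specificity = TN/(TN+FP); MCC = (TP TN - FP FN)/sqrt(prod of margins).
    Metrics with a zero denominator are reported as NaN (undefined), not 0.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    tpr = _safe_div(tp, tp + fn)
    fpr = _safe_div(fp, tn + fp)
    precision = _safe_div(tp, tp + fp)
    accuracy = (tp + tn) / counts.total
    f1 = _safe_div(2 * precision * tpr, precision + tpr) \
        if not (math.isnan(precision) or math.isnan(tpr)) else float("nan")
    specificity = _safe_div(tn, tn + fp)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom)
    return {"TPR": tpr, "FPR": fpr, "Precision": precision,
            "Accuracy": accuracy, "F1": f1, "Specificity": specificity,
            "MCC": mcc}


class InterfaceClassifier(BaseEstimator, ClassifierMixin):
    """Native-like vs non-native interface classifier emitting the PI-score.

    Parameters
    ----------
    algorithm : {"svm", "rf", "nn", "gb"}
        Learner. "svm" (the default, RBF kernel, C=1, gamma="scale") defines
        the PI-score as the raw SVM decision value; the alternatives expose a
        comparable signed score 2*P(native) - 1.
    kernel : str
        SVM kernel ("rbf" or "linear"); ignored by other algorithms.
    standardize : bool
        Fit a StandardScaler on the training data (recommended; the features
        mix counts, fractions, energies and areas).
    random_state : int
        Seed for the stochastic learners.
    """

    def __init__(self, algorithm: str = "svm", kernel: str = "rbf",
                 C: float = 1.0, standardize: bool = True,
                 random_state: int = 0):
        self.algorithm = algorithm
        self.kernel = kernel
        self.C = C
        self.standardize = standardize
        self.random_state = random_state

    def _make_estimator(self):
        if self.algorithm == "svm":
            return SVC(kernel=self.kernel, C=self.C, gamma="scale")
        if self.algorithm == "rf":
            return RandomForestClassifier(n_estimators=200,
                                          random_state=self.random_state)
        if self.algorithm == "nn":
            return MLPClassifier(hidden_layer_sizes=(32, 16), max_iter=2000,
                                 random_state=self.random_state)
        if self.algorithm == "gb":
            return GradientBoostingClassifier(random_state=self.random_state)
        raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("training data must contain both classes")
        self.classes_ = classes
        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            X = self.scaler_.transform(X)
        else:
            self.scaler_ = None
        self.estimator_ = self._make_estimator().fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _transform(self, X):
        X = check_array(X)
        return self.scaler_.transform(X) if self.scaler_ is not None else X

    def decision_function(self, X):
        """PI-score: signed decision value; positive = native-like."""
        check_is_fitted(self, "estimator_")
        X = self._transform(X)
        if self.algorithm == "svm":
            return self.estimator_.decision_function(X)
        proba = self.estimator_.predict_proba(X)[:, list(self.estimator_.classes_).index(1)]
        return 2.0 * proba - 1.0

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


def pi_score(model: InterfaceClassifier, features) -> float | np.ndarray:
    """Signed PI-score(s) of feature vector(s) under a trained classifier."""
    check_is_fitted(model, "estimator_")
    arr = np.asarray(features, dtype=float)
    single = arr.ndim == 1
    scores = model.decision_function(arr.reshape(1, -1) if single else arr)
    return float(scores[0]) if single else scores


def train_classifier(dataset: LabeledDataset, algorithm: str = "svm",
                     kernel: str = "rbf", test_fraction: float = 0.30,
                     n_splits: int = 10, seed: int = 0,
                     standardize: bool = True,
                     model_variant: str = "B"
                     ) -> tuple[InterfaceClassifier, pd.DataFrame]:
    """Cross-validate and fit the interface classifier.

    Performs `n_splits` independent stratified train/test resamples (test
    fraction 0.30 by default), reporting accuracy, precision, recall, F1 and
    MCC per split with standardization fitted on each training split only;
    then refits on the full dataset. `model_variant` "A" uses only decoy-
    derived rows (PD2+ND, by provenance); "B" uses everything.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0,1)")
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if model_variant == "A" and dataset.provenance is not None:
        dataset = dataset.subset(dataset.provenance != "PD1")
    X, y = dataset.X, dataset.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")

    splitter = StratifiedShuffleSplit(n_splits=n_splits, test_size=test_fraction,
                                      random_state=seed)
    rows = []
    for k, (tr, te) in enumerate(splitter.split(X, y)):
        clf = InterfaceClassifier(algorithm=algorithm, kernel=kernel,
                                  standardize=standardize, random_state=seed)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        counts = ConfusionCounts(
            tp=int(np.sum((pred == 1) & (y[te] == 1))),
            tn=int(np.sum((pred == 0) & (y[te] == 0))),
            fp=int(np.sum((pred == 1) & (y[te] == 0))),
            fn=int(np.sum((pred == 0) & (y[te] == 1))))
        m = confusion_metrics(counts)
        rows.append({"split": k, "accuracy": m["Accuracy"],
                     "precision": m["Precision"], "recall": m["TPR"],
                     "f1": m["F1"], "mcc": m["MCC"]})
    report = pd.DataFrame(rows)
    final = InterfaceClassifier(algorithm=algorithm, kernel=kernel,
                                standardize=standardize, random_state=seed)
    final.fit(X, y)
    return final, report


# -- score-bin performance (mirrored bins) ------------------------------------

_BIN_EDGES = [(0.0, 0.5), (0.5, 1.0), (1.0, 1.5), (1.5, 2.0), (2.0, 2.5)]


def binned_performance(scores, labels) -> pd.DataFrame:
    """Per-bin performance of the signed score in mirrored 0.5-wide bins.

    For bin (lo, hi]: TP = positives with score in (lo, hi]; TN = negatives
    with score in [-hi, -lo); FP = negatives (mis)predicted positive with
    score in (lo, hi]; FN = positives predicted negative with score in
    [-hi, -lo). The open tail pairs score >= 2.5 with score <= -2.5. Empty
    bins are reported with NaN metrics rather than dropped.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels differ in length")
    rows = []

    def bin_row(label, pos_mask, neg_mask):
        counts = ConfusionCounts(
            tp=int(np.sum(pos_mask & (labels == 1))),
            fp=int(np.sum(pos_mask & (labels == 0))),
            tn=int(np.sum(neg_mask & (labels == 0))),
            fn=int(np.sum(neg_mask & (labels == 1))))
        if counts.total == 0:
            m = dict.fromkeys(("TPR", "FPR", "Precision", "Specificity"), float("nan"))
        else:
            m = confusion_metrics(counts)
        rows.append({"bin": label, "TP": counts.tp, "TN": counts.tn,
                     "FP": counts.fp, "FN": counts.fn,
                     "TPR": m["TPR"], "FPR": m["FPR"],
                     "Precision": m["Precision"], "Specificity": m["Specificity"]})

    for lo, hi in _BIN_EDGES:
        pos = (scores > lo) & (scores <= hi)
        neg = (scores < -lo) & (scores >= -hi)
        bin_row(f"(-/+)[{lo:.1f} to {hi:.1f}]", pos, neg)
    bin_row(">=2.5 and <=-2.5", scores >= 2.5, scores <= -2.5)
    return pd.DataFrame(rows)


def rank_features(dataset: LabeledDataset, seed: int = 0,
                  n_seeds_rf: int = 1) -> pd.DataFrame:
    """Mean normalized feature-importance rank across five ranking methods.

    Methods: Ridge, random forest, recursive feature elimination, linear
    regression and Lasso (sklearn defaults). Each method's importances are
    min-max normalized to [0, 1] (1 = most important); the mean across
    methods is returned per feature, sorted descending.
    """
    X = StandardScaler().fit_transform(dataset.X)
    y = dataset.y.astype(float)
    importances = {}
    importances["ridge"] = np.abs(Ridge().fit(X, y).coef_)
    importances["random_forest"] = RandomForestClassifier(
        n_estimators=200, random_state=seed).fit(X, dataset.y).feature_importances_
    rfe = RFE(LinearRegression(), n_features_to_select=1).fit(X, y)
    importances["rfe"] = (rfe.ranking_.max() - rfe.ranking_).astype(float)
    importances["linear_regression"] = np.abs(LinearRegression().fit(X, y).coef_)
    importances["lasso"] = np.abs(Lasso(alpha=0.01, random_state=seed).fit(X, y).coef_)

    norm = {}
    for name, imp in importances.items():
        rng_ = imp.max() - imp.min()
        norm[name] = (imp - imp.min()) / rng_ if rng_ > 0 else np.full_like(imp, 0.5)
    df = pd.DataFrame(norm, index=list(dataset.feature_names))
    df["mean_rank"] = df.mean(axis=1)
    return df.sort_values("mean_rank", ascending=False)


def casp_agreement(external_scores: dict[str, list[float]],
                   predictions: dict[str, float],
                   threshold: float = 0.5) -> ConfusionCounts:
    """Agreement between per-model mean PI-score sign and external assembly scores.

    A model counts as externally good when at least one of its external
    scores is >= threshold. TP: externally good and predicted positive;
    TN: externally poor and predicted negative; FP: externally poor but
    predicted positive; FN: externally good but predicted negative.
    `predictions` maps model id -> mean PI-score over its interfaces.
    """
    missing = sorted(set(external_scores) ^ set(predictions))
    if missing:
        raise KeyError(f"model ids missing from one table: {missing}")
    tp = tn = fp = fn = 0
    for model_id, ext in external_scores.items():
        good = any(s >= threshold for s in ext)
        positive = predictions[model_id] > 0
        if good and positive:
            tp += 1
        elif not good and not positive:
            tn += 1
        elif not good and positive:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


# -- model serialization (text, SVM only) -------------------------------------

_MODEL_FORMAT_VERSION = 1


def save_model(model: InterfaceClassifier, path: str | Path,
               training_checksum: str | None = None) -> None:
    """Serialize a fitted SVM classifier to a versioned JSON file."""
    check_is_fitted(model, "estimator_")
    if model.algorithm != "svm":
        raise ValueError("only SVM models serialize to the text format; "
                         "refit with algorithm='svm'")
    est: SVC = model.estimator_
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "config": model.get_params(),
        "feature_names": list(FEATURE_NAMES),
        "classes": est.classes_.tolist(),
        "scaler_mean": model.scaler_.mean_.tolist() if model.scaler_ else None,
        "scaler_scale": model.scaler_.scale_.tolist() if model.scaler_ else None,
        "support_vectors": est.support_vectors_.tolist(),
        "dual_coef": est.dual_coef_.tolist(),
        "intercept": est.intercept_.tolist(),
        "gamma": float(est._gamma),
        "n_support": est.n_support_.tolist(),
        "training_checksum": training_checksum,
    }
    Path(path).write_text(json.dumps(payload))


class _SVMDecision:
    """Explicit SVM decision surface rebuilt from serialized parameters.

    f(x) = sum_j alpha_j K(sv_j, x) + b, with K either RBF or linear; the
    sign convention matches sklearn's SVC (positive -> classes_[1]).
    """

    def __init__(self, kernel, gamma, support_vectors, dual_coef, intercept, classes):
        self.kernel = kernel
        self.gamma = gamma
        self.support_vectors = np.asarray(support_vectors, dtype=float)
        self.dual_coef = np.asarray(dual_coef, dtype=float).ravel()
        self.intercept = float(np.asarray(intercept).ravel()[0])
        self.classes_ = np.asarray(classes)

    def decision_function(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.kernel == "linear":
            K = X @ self.support_vectors.T
        else:
            d2 = np.sum((X[:, None, :] - self.support_vectors[None, :, :]) ** 2, axis=2)
            K = np.exp(-self.gamma * d2)
        return K @ self.dual_coef + self.intercept

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def load_model(path: str | Path) -> InterfaceClassifier:
    """Load a classifier saved by `save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    model = InterfaceClassifier(**payload["config"])
    sv = np.array(payload["support_vectors"])
    model.estimator_ = _SVMDecision(
        kernel=model.kernel, gamma=payload["gamma"],
        support_vectors=sv, dual_coef=payload["dual_coef"],
        intercept=payload["intercept"], classes=payload["classes"])
    if payload["scaler_mean"] is not None:
        scaler = StandardScaler()
        scaler.mean_ = np.array(payload["scaler_mean"])
        scaler.scale_ = np.array(payload["scaler_scale"])
        scaler.var_ = scaler.scale_ ** 2
        scaler.n_features_in_ = len(scaler.mean_)
        scaler.n_samples_seen_ = 1
        model.scaler_ = scaler
    else:
        model.scaler_ = None
    model.classes_ = model.estimator_.classes_
    model.n_features_in_ = sv.shape[1]
    return model


def dataset_checksum(dataset: LabeledDataset) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(dataset.X).tobytes())
    h.update(np.ascontiguousarray(dataset.y).tobytes())
    return h.hexdigest()[:16]
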