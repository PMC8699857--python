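"""Classification and the repeated leave-30-out evaluation protocol.

The diagnostic classifier is an RBF-kernel SVM whose (C, gamma) are chosen
by 5-fold grid search on the training fold only; k-NN (k = 5) and LDA serve
as comparators.  Generalization is measured by 10 repetitions of a
stratified leave-k-out split: each repetition holds out 30 subjects — 15
patients and 15 controls, with every House-Brackmann grade II–V represented
by at least one test patient — trains on the remaining 60, and reports the
confusion-matrix metrics

    accuracy     = (TP + TN) / (TP + TN + FP + FN)
    sensitivity  = TP / (TP + FN)
    specificity  = TN / (FP + TN)
    precision    = TP / (FP + TP)
    F1           = 2 * precision * sensitivity / (precision + sensitivity)

plus the trapezoidal ROC AUC of the continuous decision scores.  Reported
performance is the mean over the 10 repetitions.  Feature standardization
and (in leak-free mode) t-test feature selection are fitted on the training
fold only, never on held-out subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .errors import ConstraintError, GroupingError, ModelingError, SizeError
from .stats_select import NEGATIVE_GROUP, POSITIVE_GROUP, TTestSelector

UNDEFINED = float("nan")

HB_COVERAGE = ("II", "III", "IV", "V")


@dataclass
class CVConfig:
    """Stratified leave-k-out protocol parameters."""

    k_test: int = 30
    repetitions: int = 10
    n_test_pos: int = 15
    n_test_neg: int = 15
    hb_coverage: tuple[str, ...] = HB_COVERAGE
    seed: int = 0

    def __post_init__(self):
        if self.n_test_pos + self.n_test_neg != self.k_test:
            raise ConstraintError("test quotas must sum to k_test")


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ModelingError("negative confusion-matrix count")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def confusion_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, precision, F1 from raw counts.

    Zero-denominator rates are reported as NaN sentinels.  ``f_alt`` is an
    additional diagnostic combining precision with specificity instead of
    sensitivity; it is never a substitute for F1.
    """
    if cm.total < 1:
        raise SizeError("empty confusion matrix")

    def ratio(num, den):
        return num / den if den > 0 else UNDEFINED

    accuracy = ratio(cm.tp + cm.tn, cm.total)
    sensitivity = ratio(cm.tp, cm.tp + cm.fn)
    specificity = ratio(cm.tn, cm.fp + cm.tn)
    precision = ratio(cm.tp, cm.fp + cm.tp)
    f1 = ratio(2 * precision * sensitivity, precision + sensitivity)
    f_alt = ratio(2 * precision * specificity, precision + specificity)
    return {
        "accuracy": accuracy,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "f1": f1,
        "f_alt": f_alt,
    }


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """Trapezoidal AUC plus the ROC points (fpr, tpr) of binary labels."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise GroupingError("ROC needs both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return auc, np.column_stack([fpr, tpr])


def standardize(train: np.ndarray, apply_to: np.ndarray | None = None):
    """Z-score features using training mean/SD only.

    Zero-variance training columns pass through unscaled.  Returns
    ``(scaled_train, scaled_apply_to, scaler)``.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise SizeError("empty training matrix")
    scaler = StandardScaler().fit(train)
    out_train = scaler.transform(train)
    out_other = scaler.transform(np.asarray(apply_to, dtype=float)) \
        if apply_to is not None else None
    return out_train, out_other, scaler


# ---------------------------------------------------------------------------
# estimator


SVM_C_GRID = (0.1, 1.0, 10.0, 100.0)
SVM_GAMMA_GRID = (0.001, 0.01, 0.1)  # plus 1/d, added at fit time


def _base_model(kind: str, n_features: int, inner_cv: int = 5, seed: int = 0):
    if kind == "svm":
        gammas = list(SVM_GAMMA_GRID) + [1.0 / max(n_features, 1)]
        return GridSearchCV(
            SVC(kernel="rbf"),
            {"C": list(SVM_C_GRID), "gamma": gammas},
            cv=inner_cv, n_jobs=1,
        )
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    raise ModelingError(f"unknown classifier kind {kind!r}")


class ThermalAsymmetryClassifier(ClassifierMixin, BaseEstimator):
    """Diagnose facial paralysis from a bilateral feature-symmetry vector.

    A scikit-learn estimator chaining optional Welch-test feature selection,
    per-feature standardization, and the classifier itself (``svm`` with
    inner grid search, ``knn``, or ``lda``), all fitted on training data
    only.

    Parameters
    ----------
    kind : {'svm', 'knn', 'lda'}, default 'svm'
    alpha : float or None, default None
        When set, keep only features with Welch p < alpha (leak-free,
        computed inside ``fit``).
    inner_cv : int, default 5
        Folds of the SVM hyperparameter search.

    Attributes
    ----------
    pipeline_ : fitted sklearn Pipeline
    classes_ : the two class labels
    n_features_selected_ : dimensionality seen by the classifier
    """

    def __init__(self, kind: str = "svm", alpha: float | None = None, inner_cv: int = 5):
        self.kind = kind
        self.alpha = alpha
        self.inner_cv = inner_cv

    def fit(self, X, y):
        X = validate_data(self, X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ModelingError("training labels must contain exactly 2 classes")
        steps = []
        if self.alpha is not None:
            steps.append(("select", TTestSelector(alpha=self.alpha)))
        steps.append(("scale", StandardScaler()))
        steps.append(("model", _base_model(self.kind, X.shape[1], self.inner_cv)))
        pipe = Pipeline(steps)
        pipe.fit(X, y)
        self.pipeline_ = pipe
        if self.alpha is not None:
            self.n_features_selected_ = int(pipe["select"].support_.sum())
        else:
            self.n_features_selected_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        return self.pipeline_.predict(validate_data(self, X, reset=False))

    def decision_function(self, X):
        """Continuous score, larger = more likely positive (for ROC)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        model = self.pipeline_
        if hasattr(model, "decision_function"):
            try:
                return model.decision_function(X)
            except AttributeError:
                pass
        proba = model.predict_proba(X)
        return proba[:, list(self.classes_).index(self.classes_[-1])]


def train_classifier(features, labels, kind: str = "svm", inner_cv: int = 5,
                     alpha: float | None = None) -> ThermalAsymmetryClassifier:
    """Fit a standardize(+select)+classify pipeline on training data only."""
    return ThermalAsymmetryClassifier(kind=kind, alpha=alpha, inner_cv=inner_cv) \
        .fit(np.asarray(features, dtype=float), np.asarray(labels))


# ---------------------------------------------------------------------------
# splits


def make_splits(metadata: pd.DataFrame, cv: CVConfig) -> list[tuple[list, list]]:
    """Repeated stratified leave-k-out splits over subject ids.

    ``metadata`` needs columns ``subject_id``, ``group`` and ``hb_grade``.
    Each repetition samples ``n_test_pos`` patients — forced to include at
    least one from every covered HB grade present in the cohort — and
    ``n_test_neg`` controls; the rest train.  Deterministic given the seed.
    """
    pos = metadata[metadata["group"] == POSITIVE_GROUP]
    neg = metadata[metadata["group"] == NEGATIVE_GROUP]
    if len(pos) < cv.n_test_pos + 1 or len(neg) < cv.n_test_neg + 1:
        raise ConstraintError("cohort too small for requested test quotas")
    covered = [g for g in cv.hb_coverage if (pos["hb_grade"] == g).any()]
    if len(covered) < len(cv.hb_coverage):
        missing = set(cv.hb_coverage) - set(covered)
        raise ConstraintError(f"cohort has no patients with HB grade(s) {sorted(missing)}")
    if len(covered) > cv.n_test_pos:
        raise ConstraintError("cannot cover all HB grades within the patient quota")
    rng = np.random.default_rng(cv.seed)
    splits = []
    all_ids = list(metadata["subject_id"])
    for _ in range(cv.repetitions):
        test: list = []
        for grade in covered:
            ids = list(pos.loc[pos["hb_grade"] == grade, "subject_id"])
            test.append(ids[rng.integers(len(ids))])
        remaining_pos = [s for s in pos["subject_id"] if s not in test]
        extra = rng.choice(len(remaining_pos), cv.n_test_pos - len(covered), replace=False)
        test.extend(remaining_pos[i] for i in extra)
        neg_ids = list(neg["subject_id"])
        picks = rng.choice(len(neg_ids), cv.n_test_neg, replace=False)
        test.extend(neg_ids[i] for i in picks)
        train = [s for s in all_ids if s not in set(test)]
        splits.append((train, test))
    return splits


# ---------------------------------------------------------------------------
# evaluation report


@dataclass
class RepetitionResult:
    confusion: ConfusionMatrix
    metrics: dict[str, float]
    auc: float
    n_features: int


@dataclass
class EvaluationReport:
    """Per-repetition results plus their averages."""

    repetitions: list[RepetitionResult]
    feature_set: str = ""
    classifier: str = "svm"
    roc_points: list = field(default_factory=list)

    @property
    def mean_metrics(self) -> dict[str, float]:
        keys = self.repetitions[0].metrics.keys()
        out = {k: float(np.nanmean([r.metrics[k] for r in self.repetitions])) for k in keys}
        out["auc"] = float(np.nanmean([r.auc for r in self.repetitions]))
        return out

    @property
    def dimensions(self) -> int:
        return self.repetitions[0].n_features

    def summary_row(self) -> dict:
        row = {"feature_set": self.feature_set, "classifier": self.classifier,
               "dimensions": self.dimensions}
        row.update(self.mean_metrics)
        return row

    def to_json(self, path=None) -> str:
        payload = {
            "feature_set": self.feature_set,
            "classifier": self.classifier,
            "mean": self.mean_metrics,
            "repetitions": [
                {"confusion": asdict(r.confusion), "metrics": r.metrics,
                 "auc": r.auc, "n_features": r.n_features}
                for r in self.repetitions
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_experiment(features: pd.DataFrame, metadata: pd.DataFrame,
                   feature_subset: list[str] | None = None,
                   cv: CVConfig | None = None, kind: str = "svm",
                   selection_alpha: float | None = None,
                   feature_set_name: str = "") -> EvaluationReport:
    """Repeated leave-k-out evaluation of one feature subset.

    Per repetition: restrict to the subset, (optionally) re-select features
    on the training fold (Welch p < ``selection_alpha``), standardize with
    training statistics, fit the classifier, and score the held-out 30.
    ``features`` is indexed by subject_id; ``metadata`` as for
    :func:`make_splits`.
    """
    cv = cv or CVConfig()
    cols = list(features.columns) if feature_subset is None else list(feature_subset)
    x = features[cols]
    labels = metadata.set_index("subject_id").loc[x.index, "group"]
    y = (labels == POSITIVE_GROUP).astype(int).to_numpy()
    reps = []
    roc_points = []
    for rep, (train_ids, test_ids) in enumerate(make_splits(metadata, cv)):
        clf = ThermalAsymmetryClassifier(kind=kind, alpha=selection_alpha)
        xtr = x.loc[train_ids].to_numpy(dtype=float)
        xte = x.loc[test_ids].to_numpy(dtype=float)
        ytr = y[[list(x.index).index(s) for s in train_ids]]
        yte = y[[list(x.index).index(s) for s in test_ids]]
        clf.fit(xtr, ytr)
        pred = clf.predict(xte)
        scores = clf.decision_function(xte)
        cm = ConfusionMatrix(
            tp=int(((pred == 1) & (yte == 1)).sum()),
            fn=int(((pred == 0) & (yte == 1)).sum()),
            fp=int(((pred == 1) & (yte == 0)).sum()),
            tn=int(((pred == 0) & (yte == 0)).sum()),
        )
        auc, points = roc_auc(scores, yte)
        roc_points.append(points)
        reps.append(RepetitionResult(confusion=cm, metrics=confusion_metrics(cm),
                                     auc=auc, n_features=clf.n_features_selected_))
    return EvaluationReport(repetitions=reps, feature_set=feature_set_name,
                            classifier=kind, roc_points=roc_points)
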