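"""Classifier evaluation under two resampling schemes.

Two validation strategies are compared on the epoch-level feature table:

* pooled stratified k-fold over epochs, which ignores subject identity and
  is therefore leakage-prone — different epochs of the same subject end up
  on both sides of the train/test split;
* leave-one-patient-out (LOPO), where each iteration holds out *all*
  epochs of one subject per class, so train and test subject sets are
  disjoint and the classifier can only exploit between-class structure.

Metrics are computed from epoch-level confusion counts with the patient
class as positive (AD or FTD vs. CN; AD for the AD/FTD problem):
accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP). Dispersion across folds/iterations is the
population standard deviation (divisor N).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureTable

CLASSIFIER_KINDS = ("decision_tree", "random_forest", "mlp", "svm", "naive_bayes", "knn")


# --------------------------------------------------------------------------
# confusion counts and metric identities
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ConfusionCounts:
    """Epoch-level confusion counts with the patient class as positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive: str) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        pos_t = y_true == positive
        pos_p = y_pred == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity); undefined denominators -> NaN."""
    if c.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    accuracy = (c.tp + c.tn) / c.total
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    specificity = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    return accuracy, sensitivity, specificity


def positive_class(classes: tuple[str, ...] | list[str]) -> str:
    """The patient class of a pairwise problem: non-CN, or AD for AD/FTD."""
    classes = sorted(set(classes))
    if len(classes) != 2:
        raise ValueError(f"expected a pairwise problem, got classes {classes}")
    if "CN" in classes:
        return next(c for c in classes if c != "CN")
    return "AD" if "AD" in classes else classes[0]


# --------------------------------------------------------------------------
# classifiers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected one of {CLASSIFIER_KINDS}")


class ReducedErrorPrunedTree(BaseEstimator, ClassifierMixin):
    """Entropy decision tree with reduced-error-style pruning.

    Emulates a C4.5 tree with reduced-error pruning: a third of the
    training data is held out, the cost-complexity pruning path is computed
    on the rest, the pruning strength maximizing held-out accuracy is
    selected, and the tree is refit on all training data at that strength.
    """

    def __init__(self, random_state: int | None = None):
        self.random_state = random_state

    def fit(self, X, y):
        base = DecisionTreeClassifier(criterion="entropy", random_state=self.random_state)
        X = np.asarray(X)
        y = np.asarray(y)
        try:
            X_grow, X_prune, y_grow, y_prune = train_test_split(
                X, y, test_size=1 / 3, stratify=y, random_state=self.random_state)
        except ValueError:  # too few samples per class to stratify
            X_grow, y_grow, X_prune, y_prune = X, y, X, y
        path = clone(base).fit(X_grow, y_grow).cost_complexity_pruning_path(X_grow, y_grow)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
        best_alpha, best_score = 0.0, -np.inf
        for alpha in alphas:
            tree = clone(base).set_params(ccp_alpha=float(alpha)).fit(X_grow, y_grow)
            score = tree.score(X_prune, y_prune)
            # on ties prefer the stronger pruning, as REP does
            if score > best_score or (score == best_score and alpha > best_alpha):
                best_alpha, best_score = float(alpha), score
        self.ccp_alpha_ = best_alpha
        self.tree_ = clone(base).set_params(ccp_alpha=best_alpha).fit(X, y)
        self.classes_ = self.tree_.classes_
        return self

    def predict(self, X):
        return self.tree_.predict(X)


def build_estimator(spec: ClassifierSpec, seed: int | None = 0):
    """Instantiate the scikit-learn estimator for a classifier spec.

    Features are standardized (training statistics only, via Pipeline) for
    the scale-sensitive learners (MLP, SVM, kNN); trees, forests and
    Gaussian naive Bayes consume raw features.
    """
    hp = dict(spec.hyperparameters)
    if spec.kind == "decision_tree":
        return ReducedErrorPrunedTree(random_state=seed, **hp)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.kind == "naive_bayes":
        return GaussianNB(**hp)
    if spec.kind == "knn":
        hp.setdefault("n_neighbors", 1)
        return Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier(**hp))])
    if spec.kind == "svm":
        hp.setdefault("kernel", "linear")
        hp.setdefault("C", 1.0)
        return Pipeline([("scale", StandardScaler()), ("clf", SVC(random_state=seed, **hp))])
    if spec.kind == "mlp":
        # hidden width: Weka-style (n_features + n_classes) / 2, resolved at fit time
        hp.setdefault("max_iter", 500)
        return Pipeline([("scale", StandardScaler()),
                         ("clf", _AutoWidthMLP(random_state=seed, **hp))])
    raise AssertionError(spec.kind)


class _AutoWidthMLP(MLPClassifier):
    """MLP whose single hidden layer is sized (n_features + n_classes)/2."""

    def fit(self, X, y):
        width = max(2, (np.asarray(X).shape[1] + len(np.unique(y))) // 2)
        self.hidden_layer_sizes = (width,)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at max_iter
            return super().fit(X, y)


def fit_predict(clf: ClassifierSpec, train: FeatureTable, test: FeatureTable,
                seed: int | None = 0) -> np.ndarray:
    """Fit on the training table and predict labels for the test rows.

    Only the feature columns are used; the class label column and the
    out-of-band subject ids are never inputs to the learner.
    """
    if len(set(train.y)) < 2:
        raise ValueError("training table must contain both classes")
    est = build_estimator(clf, seed=seed)
    est.fit(train.X, train.y)
    return np.asarray(est.predict(test.X))


# --------------------------------------------------------------------------
# resampling schemes
# --------------------------------------------------------------------------
@dataclass
class FoldResult:
    held_out: str
    counts: ConfusionCounts
    accuracy: float
    sensitivity: float
    specificity: float

    @classmethod
    def from_counts(cls, held_out: str, counts: ConfusionCounts) -> "FoldResult":
        acc, sens, spec = confusion_metrics(counts)
        return cls(held_out, counts, acc, sens, spec)


@dataclass
class CVSummary:
    """Per-fold metrics with mean and population SD (divisor N)."""

    scheme: str  # "kfold" or "lopo"
    classifier: str
    folds: list[FoldResult]

    def _stat(self, attr: str) -> tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.folds], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=0))

    @property
    def mean_accuracy(self) -> float:
        return self._stat("accuracy")[0]

    @property
    def sd_accuracy(self) -> float:
        return self._stat("accuracy")[1]

    @property
    def mean_sensitivity(self) -> float:
        return self._stat("sensitivity")[0]

    @property
    def mean_specificity(self) -> float:
        return self._stat("specificity")[0]

    @property
    def n_iterations(self) -> int:
        return len(self.folds)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "classifier": self.classifier,
            "n_iterations": self.n_iterations,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_sensitivity": self.mean_sensitivity,
            "mean_specificity": self.mean_specificity,
            "folds": [
                {
                    "held_out": f.held_out,
                    "tp": f.counts.tp, "tn": f.counts.tn,
                    "fp": f.counts.fp, "fn": f.counts.fn,
                    "accuracy": f.accuracy,
                    "sensitivity": f.sensitivity,
                    "specificity": f.specificity,
                }
                for f in self.folds
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def fold_frame(self) -> pd.DataFrame:
        """Tidy per-fold table, one row per fold."""
        return pd.DataFrame(self.to_dict()["folds"]).assign(
            scheme=self.scheme, classifier=self.classifier)


def population_sd(values) -> float:
    """Standard deviation with divisor N (not N-1)."""
    return float(np.std(np.asarray(values, dtype=float), ddof=0))


def pooled_kfold_cv(table: FeatureTable, clf: ClassifierSpec, k: int = 10,
                    seed: int = 0) -> CVSummary:
    """Stratified k-fold over pooled epochs, ignoring subject identity.

    This deliberately allows epochs of the same subject on both sides of
    the split — the leakage-prone design under study.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(table) < k:
        raise ValueError(f"table has {len(table)} rows, fewer than k={k}")
    pos = positive_class(tuple(set(table.y)))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    y = table.y
    for i, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(table)), y)):
        train_mask = np.zeros(len(table), dtype=bool)
        train_mask[train_idx] = True
        if len(set(y[train_idx])) < 2:
            warnings.warn(f"fold {i}: a class is absent from training, skipping")
            continue
        pred = fit_predict(clf, table.subset(train_mask), table.subset(~train_mask), seed=seed)
        counts = ConfusionCounts.from_labels(y[test_idx], pred, positive=pos)
        folds.append(FoldResult.from_counts(f"fold-{i}", counts))
    return CVSummary("kfold", clf.kind, folds)


def lopo_iterations(groups: dict[str, str]) -> list[tuple[str, ...]]:
    """Held-out subject tuples for leave-one-patient-out validation.

    One subject per class is held out per iteration. With unequal class
    sizes the iteration count is the larger class size and the smaller
    class is reused round-robin (subject i mod n), so every subject is
    tested at least once while every test set still contains one subject
    of each class.
    """
    by_class: dict[str, list[str]] = {}
    for subject in sorted(groups):
        by_class.setdefault(groups[subject], []).append(subject)
    for cls, subjects in by_class.items():
        if len(subjects) < 2:
            raise ValueError(f"class {cls!r} has a single subject; cannot leave one out")
    n_iter = max(len(s) for s in by_class.values())
    return [
        tuple(subjects[i % len(subjects)] for subjects in by_class.values())
        for i in range(n_iter)
    ]


def lopo_cv(table: FeatureTable, groups: dict[str, str] | None, clf: ClassifierSpec,
            seed: int = 0) -> CVSummary:
    """Leave-one-patient-out: hold out all epochs of one subject per class."""
    if groups is None:
        groups = table.groups()
    pos = positive_class(tuple(set(groups.values())))
    subjects = table.subject_ids.to_numpy()
    folds = []
    for held in lopo_iterations(groups):
        test_mask = np.isin(subjects, held)
        if not test_mask.any():
            raise ValueError(f"held-out subjects {held} have no epochs in the table")
        pred = fit_predict(clf, table.subset(~test_mask), table.subset(test_mask), seed=seed)
        counts = ConfusionCounts.from_labels(table.y[test_mask], pred, positive=pos)
        folds.append(FoldResult.from_counts("+".join(held), counts))
    return CVSummary("lopo", clf.kind, folds)
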