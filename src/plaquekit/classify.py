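"""Supervised staging: split, hyperparameter tuning, the OvO margin SVM, metrics.

The three classifiers mirror the staging study's setup: k-nearest neighbours
(neighbour count and distance metric tuned), a decision tree (depth, leaf
size, split counts tuned), and a multiclass SVM built from all one-vs-one
binary SVMs decoded by majority vote with the aggregate margin distance as
the confidence tie-break.

:class:`TunedClassifier` performs a seeded random search over each
algorithm's hyperparameter space, scoring configurations by stratified
k-fold (default tenfold) cross-validated misclassification loss on the
training partition only, then refits the best configuration on the full
training set.  Its ``generalization_error_`` is the train accuracy minus the
mean cross-validation accuracy of the selected configuration — the
overfitting gap.

Features are standardized inside the distance-based models (kNN, SVM); the
decision tree is scale-invariant and consumes raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import (
    ParameterSampler,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CLASS_ORDER",
    "split_dataset",
    "OneVsOneMarginSVC",
    "TunedClassifier",
    "EvaluationReport",
    "evaluate",
]

#: Fixed class encoding: EFS=0, EF=1, AA=2.
CLASS_ORDER = ("EFS", "EF", "AA")

_SEED_MOD = 2**31 - 1


def split_dataset(
    table: pd.DataFrame,
    train_frac: float = 0.6,
    test_frac: float = 0.2,
    val_frac: float = 0.2,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test/validation partition of a feature table.

    Stratification preserves per-class proportions within rounding.  The
    partition is a pure function of ``(table, fractions, seed)``.
    """
    fracs = np.array([train_frac, test_frac, val_frac])
    if (fracs <= 0).any() or not np.isclose(fracs.sum(), 1.0):
        raise ValueError("fractions must be positive and sum to 1")
    def _split(df, size, rs, strat):
        try:
            return train_test_split(df, train_size=size, random_state=rs,
                                    stratify=strat)
        except ValueError:
            if strat is None:
                raise
            # too few members per class to stratify: fall back to plain split
            return train_test_split(df, train_size=size, random_state=rs)

    strat = table["label"] if stratify else None
    train, rest = _split(table, train_frac, seed % _SEED_MOD, strat)
    rel_test = test_frac / (test_frac + val_frac)
    strat_rest = rest["label"] if stratify else None
    test, val = _split(rest, rel_test, (seed + 1) % _SEED_MOD, strat_rest)
    return (
        train.reset_index(drop=True),
        test.reset_index(drop=True),
        val.reset_index(drop=True),
    )


class OneVsOneMarginSVC(BaseEstimator, ClassifierMixin):
    """Multiclass SVM from all pairwise binary SVMs, decoded by vote + margin.

    One binary SVM is trained per class pair (three learners for three
    classes).  Prediction is by majority vote over the pairwise decisions;
    a tied vote (e.g. a three-way cycle) is broken by the largest aggregate
    signed margin distance accumulated over all binary learners.
    """

    def __init__(self, C: float = 1.0, gamma="scale", kernel: str = "rbf"):
        self.C = C
        self.gamma = gamma
        self.kernel = kernel

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        self.estimators_ = {}
        for a_idx in range(len(self.classes_)):
            for b_idx in range(a_idx + 1, len(self.classes_)):
                a, b = self.classes_[a_idx], self.classes_[b_idx]
                sel = (y == a) | (y == b)
                svc = SVC(C=self.C, gamma=self.gamma, kernel=self.kernel)
                svc.fit(X[sel], y[sel])
                self.estimators_[(a_idx, b_idx)] = svc
        return self

    def decision_components(self, X):
        """Per-class vote counts and aggregate margins, shape (n, n_classes) each."""
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=np.float64)
        n, c = X.shape[0], len(self.classes_)
        votes = np.zeros((n, c))
        margins = np.zeros((n, c))
        for (a_idx, b_idx), svc in self.estimators_.items():
            d = svc.decision_function(X)
            # positive decision favours svc.classes_[1]
            pos_idx = b_idx if svc.classes_[1] == self.classes_[b_idx] else a_idx
            neg_idx = a_idx if pos_idx == b_idx else b_idx
            votes[:, pos_idx] += d > 0
            votes[:, neg_idx] += d <= 0
            margins[:, pos_idx] += d
            margins[:, neg_idx] -= d
        return votes, margins

    def predict(self, X):
        votes, margins = self.decision_components(X)
        # majority vote; ties broken by the largest aggregate margin
        best = np.zeros(votes.shape[0], dtype=int)
        for i in range(votes.shape[0]):
            top = votes[i].max()
            tied = np.flatnonzero(votes[i] == top)
            best[i] = tied[np.argmax(margins[i, tied])]
        return self.classes_[best]


def _space(algorithm: str, seed: int):
    """Hyperparameter space and base estimator for one algorithm."""
    if algorithm == "knn":
        est = Pipeline(
            [("scale", StandardScaler()), ("model", KNeighborsClassifier())]
        )
        space = {
            "model__n_neighbors": randint(1, 31),
            "model__metric": ["euclidean", "cityblock", "chebyshev", "cosine"],
            "model__weights": ["uniform", "distance"],
        }
    elif algorithm == "dt":
        est = DecisionTreeClassifier(random_state=seed % _SEED_MOD)
        space = {
            "max_depth": randint(1, 21),
            "min_samples_leaf": randint(1, 21),
            "min_samples_split": randint(2, 21),
            "max_leaf_nodes": randint(4, 65),
        }
    elif algorithm == "mcsvm":
        est = Pipeline(
            [("scale", StandardScaler()), ("model", OneVsOneMarginSVC())]
        )
        space = {
            "model__C": loguniform(1e-2, 1e3),
            "model__gamma": loguniform(1e-4, 1e1),
            "model__kernel": ["rbf", "linear"],
        }
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return est, space


class TunedClassifier(BaseEstimator, ClassifierMixin):
    """Seeded random-search tuning of one staging classifier.

    Parameters
    ----------
    algorithm : {"knn", "dt", "mcsvm"}
    budget : int, default 30
        Number of sampled configurations; 0 trains at the space defaults.
    cv_folds : int, default 10
        Stratified k-fold cross-validation within the training data (capped
        at the smallest class count).
    seed : int
        Controls sampling, fold shuffling and any stochastic base learner.

    Attributes
    ----------
    best_params_, best_loss_ : selected configuration and its CV loss.
    cv_results_ : list of (params, mean CV loss) over the whole trace.
    train_accuracy_, cv_accuracy_, generalization_error_ : overfitting gap
        diagnostics; ``generalization_error_ = train_accuracy_ - cv_accuracy_``.
    """

    def __init__(
        self,
        algorithm: str = "dt",
        budget: int = 30,
        cv_folds: int = 10,
        seed: int = 0,
    ):
        self.algorithm = algorithm
        self.budget = budget
        self.cv_folds = cv_folds
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        est, space = _space(self.algorithm, self.seed)
        _, counts = np.unique(y, return_counts=True)
        folds = int(min(self.cv_folds, counts.min()))
        if folds < 2:
            raise ValueError("need at least 2 samples per class for cross-validation")
        cv = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=self.seed % _SEED_MOD
        )
        candidates = (
            list(
                ParameterSampler(
                    space, n_iter=self.budget, random_state=self.seed % _SEED_MOD
                )
            )
            if self.budget > 0
            else [{}]
        )
        # neighbour counts beyond the smallest CV training fold are infeasible
        max_k = max(1, (len(X) * (folds - 1)) // folds)
        trace = []
        best_loss, best_params = np.inf, {}
        for params in candidates:
            if "model__n_neighbors" in params:
                params = dict(params)
                params["model__n_neighbors"] = int(
                    min(params["model__n_neighbors"], max_k)
                )
            model = clone(est).set_params(**params)
            try:
                acc = cross_val_score(
                    model, X, y, cv=cv, scoring="accuracy", error_score=np.nan
                )
                loss = (
                    float(1.0 - np.nanmean(acc))
                    if not np.isnan(acc).all()
                    else np.inf
                )
            except ValueError:  # infeasible configuration: skip, not fatal
                loss = np.inf
            trace.append((params, loss))
            if loss < best_loss:
                best_loss, best_params = loss, params
        if not np.isfinite(best_loss):
            # every sampled configuration failed: fall back to the defaults
            best_params = {}
            acc = cross_val_score(clone(est), X, y, cv=cv, scoring="accuracy")
            best_loss = float(1.0 - acc.mean())
        self.model_ = clone(est).set_params(**best_params).fit(X, y)
        self.classes_ = np.unique(y)
        self.cv_results_ = trace
        self.best_params_ = best_params
        self.best_loss_ = best_loss
        self.train_accuracy_ = float((self.model_.predict(X) == y).mean())
        self.cv_accuracy_ = 1.0 - best_loss
        self.generalization_error_ = self.train_accuracy_ - self.cv_accuracy_
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(np.asarray(X, dtype=np.float64))


@dataclass
class EvaluationReport:
    """Confusion matrix and per-class/macro staging metrics.

    Per-class accuracy is the within-class hit rate (identical to recall);
    precision/recall/F1 are one-vs-rest.  ``generalization_error`` is the
    train-minus-CV accuracy gap of the evaluated model, when known.
    """

    labels: list[str]
    confusion: np.ndarray  # rows = true, cols = predicted
    per_class: dict[str, dict[str, float]]
    macro: dict[str, float]
    generalization_error: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab in self.labels:
            for metric, value in self.per_class[lab].items():
                rows.append({"class": lab, "metric": metric, "value": value})
        for metric, value in self.macro.items():
            rows.append({"class": "macro", "metric": metric, "value": value})
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "macro": self.macro,
            "generalization_error": self.generalization_error,
        }


def evaluate(
    model,
    X,
    y_true,
    labels=CLASS_ORDER,
    generalization_error: float | None = None,
) -> EvaluationReport:
    """Evaluate a fitted model on a held-out set."""
    y_true = np.asarray(y_true)
    if y_true.size == 0:
        raise ValueError("empty evaluation set")
    y_pred = model.predict(np.asarray(X, dtype=np.float64))
    labels = [l for l in labels if l in set(y_true) | set(y_pred)] or list(labels)
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    per_class = {}
    for i, lab in enumerate(labels):
        tp = cm[i, i]
        fn = cm[i].sum() - tp
        fp = cm[:, i].sum() - tp
        support = cm[i].sum()
        recall = tp / support if support else 0.0
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        per_class[lab] = {
            "accuracy": float(recall),
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
        }
    macro = {
        m: float(np.mean([per_class[lab][m] for lab in labels]))
        for m in ("accuracy", "precision", "recall", "f1")
    }
    macro["overall_accuracy"] = float(np.trace(cm) / cm.sum())
    if generalization_error is None and hasattr(model, "generalization_error_"):
        generalization_error = float(model.generalization_error_)
    return EvaluationReport(
        labels=list(labels),
        confusion=cm,
        per_class=per_class,
        macro=macro,
        generalization_error=generalization_error,
    )
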