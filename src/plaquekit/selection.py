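"""Feature refinement: interclass coefficient-of-variation and chi-square filter.

Two estimators narrow the 27-feature panel before classification:

* :class:`CVThresholdSelector` — the interclass coefficient-of-variation
  method.  Per feature, the three class-conditional means are reduced to
  ``CV% = 100 * sd(class means) / mean(class means)`` (sample, n-1, standard
  deviation).  Features whose CV strictly exceeds the threshold (default 8%)
  vary enough between disease stages to carry predictive power and are
  retained.  The score is scale-invariant, so raw and normalized feature
  values select identically.

* :class:`ChiSquareSelector` — classical filter-type selection.  Each feature
  is discretized into equal-frequency bins and scored by the chi-square test
  of independence between the binned feature and the class label; the top-k
  (default 15) features by ascending p-value are retained.

Both implement the sklearn selector protocol (``fit``/``transform``/
``get_support``) and accept a plain feature matrix with labels, or the
package's feature-table DataFrame via the module-level helpers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .features import FEATURE_NAMES

__all__ = [
    "class_means",
    "CVThresholdSelector",
    "ChiSquareSelector",
    "SelectionResult",
    "cv_select",
    "ftf_select",
]


def class_means(table: pd.DataFrame, feature_names=None) -> pd.DataFrame:
    """Class-conditional means: one row per class, one column per feature.

    Raises if any class present in the label column has no rows — which
    cannot happen — so in practice this errors only when ``table`` is empty.
    """
    feature_names = list(feature_names or FEATURE_NAMES)
    if "label" not in table.columns:
        raise ValueError("table must have a 'label' column")
    if len(table) == 0:
        raise ValueError("empty feature table")
    return table.groupby("label", sort=True)[feature_names].mean()


@dataclass
class SelectionResult:
    """Outcome of one refinement method, serializable to JSON/CSV."""

    method: str  # "CV" or "FTF"
    retained: list[str]
    scores: dict[str, float]
    threshold_or_k: float

    def to_json(self, path: str) -> None:
        payload = {
            "method": self.method,
            "threshold_or_k": self.threshold_or_k,
            "retained": self.retained,
            "scores": {
                k: (v if np.isfinite(v) else "inf") for k, v in self.scores.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "SelectionResult":
        with open(path) as fh:
            payload = json.load(fh)
        scores = {
            k: (np.inf if v == "inf" else float(v))
            for k, v in payload["scores"].items()
        }
        return cls(
            method=payload["method"],
            retained=list(payload["retained"]),
            scores=scores,
            threshold_or_k=payload["threshold_or_k"],
        )

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"feature": list(self.scores), "score": list(self.scores.values())}
        ).to_csv(path, index=False)


class CVThresholdSelector(SelectorMixin, BaseEstimator):
    """Retain features whose interclass coefficient of variation exceeds a threshold.

    Parameters
    ----------
    threshold_pct : float, default 8.0
        Features with ``CV% > threshold_pct`` (strict) are retained.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        CV% per feature; ``inf`` where the grand mean of class means is 0
        (such features are retained, with a warning).
    support_ : boolean mask of retained features.
    """

    def __init__(self, threshold_pct: float = 8.0):
        self.threshold_pct = threshold_pct

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least two classes")
        means = np.stack([X[y == c].mean(axis=0) for c in classes])  # (C, F)
        sd = means.std(axis=0, ddof=1)
        grand = means.mean(axis=0)
        scores = np.empty(X.shape[1])
        zero = grand == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = 100.0 * sd / np.abs(grand)
        if zero.any():
            warnings.warn(
                "grand mean of class means is 0 for some feature(s); "
                "CV undefined, assigning +inf and retaining them",
                RuntimeWarning,
            )
            scores[zero] = np.inf
        self.class_means_ = means
        self.classes_ = classes
        self.scores_ = scores
        self.support_ = scores > self.threshold_pct
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into equal-frequency bins; degenerate bins merge."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right")


class ChiSquareSelector(SelectorMixin, BaseEstimator):
    """Rank features by chi-square independence from the class label; keep top k.

    Each feature is discretized into ``n_bins`` equal-frequency bins and the
    chi-square statistic of the (bins x classes) contingency table is
    computed.  Ranking is by ascending p-value, ties broken by descending
    statistic, then by canonical column order.  A constant feature scores 0
    and ranks last.

    Attributes
    ----------
    scores_, pvalues_ : per-feature chi-square statistic and p-value.
    ranking_ : permutation of feature indices, best first.
    support_ : boolean mask of the top ``k`` features.
    """

    def __init__(self, k: int = 15, n_bins: int = 10):
        self.k = k
        self.n_bins = n_bins

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        if self.k > X.shape[1]:
            raise ValueError("k cannot exceed the number of features")
        classes, y_enc = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least two classes")
        n_feat = X.shape[1]
        stats_ = np.zeros(n_feat)
        pvals = np.ones(n_feat)
        for j in range(n_feat):
            bins = _equal_frequency_bins(X[:, j], self.n_bins)
            table = pd.crosstab(bins, y_enc).to_numpy()
            if table.shape[0] < 2:  # constant feature: independent by fiat
                stats_[j], pvals[j] = 0.0, 1.0
                continue
            chi2, p, _, _ = stats.chi2_contingency(table)
            stats_[j], pvals[j] = chi2, p
        order = np.lexsort((np.arange(n_feat), -stats_, pvals))
        support = np.zeros(n_feat, dtype=bool)
        support[order[: self.k]] = True
        self.scores_ = stats_
        self.pvalues_ = pvals
        self.ranking_ = order
        self.support_ = support
        self.n_features_in_ = n_feat
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def _table_to_xy(table: pd.DataFrame):
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy()
    return X, y


def cv_select(table: pd.DataFrame, threshold_pct: float = 8.0) -> SelectionResult:
    """Interclass-CV refinement of a feature-table DataFrame."""
    X, y = _table_to_xy(table)
    sel = CVThresholdSelector(threshold_pct=threshold_pct).fit(X, y)
    retained = [n for n, keep in zip(FEATURE_NAMES, sel.support_) if keep]
    return SelectionResult(
        method="CV",
        retained=retained,
        scores=dict(zip(FEATURE_NAMES, map(float, sel.scores_))),
        threshold_or_k=threshold_pct,
    )


def ftf_select(table: pd.DataFrame, k: int = 15, n_bins: int = 10) -> SelectionResult:
    """Chi-square filter-type refinement of a feature-table DataFrame."""
    X, y = _table_to_xy(table)
    sel = ChiSquareSelector(k=k, n_bins=n_bins).fit(X, y)
    ranked = [FEATURE_NAMES[i] for i in sel.ranking_[:k]]
    return SelectionResult(
        method="FTF",
        retained=ranked,
        scores=dict(zip(FEATURE_NAMES, map(float, sel.scores_))),
        threshold_or_k=k,
    )
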