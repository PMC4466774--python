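"""McRank: pointwise ranking through trait discretization.

Continuous training traits are divided into B equal-width bins; each
training value is replaced by the mean of its bin, giving a finite
label set b_1 <= ... <= b_B.  Candidates are then ranked by their
expected trait value

    h(x) = sum_r Pr(y = b_r | x) * b_r,

a convex combination of bin means.  The two variants differ in how the
class probabilities are obtained:

* multiclass — one probabilistic classifier over the B bin labels
  (ignores the label ordering);
* ordinal — B-1 binary classifiers, one per cumulative cut, estimating
  F_r(x) = Pr(y <= b_r | x); class probabilities are consecutive
  differences F_r - F_{r-1}.  Because the cut classifiers are fitted
  independently, the F_r need not be monotone in r; negative
  differences are clipped to zero and the vector renormalized to sum 1,
  the minimal repair that preserves a probability vector.

The default classifier is a random forest (probability estimates from
vote fractions), which in practice outperforms logistic regression on
marker data; any classifier exposing ``predict_proba`` can be plugged
in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "BinScheme",
    "discretize_equal_width",
    "McRank",
    "fit_multiclass_mcrank",
    "fit_ordinal_mcrank",
    "mcrank_score",
]


@dataclass(frozen=True)
class BinScheme:
    """Equal-width discretization of training traits.

    ``edges`` are the original B+1 equal-width edges spanning the
    training range; ``means`` holds the per-bin training means for the
    retained (nonempty) bins only, and ``bin_of`` maps each training
    value to its retained-bin index.  Empty bins are dropped, so the
    effective bin count can be smaller than requested.
    """

    edges: np.ndarray
    means: np.ndarray
    bin_of: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.means)

    def replaced_values(self) -> np.ndarray:
        """Training trait values replaced by their bin means."""
        return self.means[self.bin_of]


def discretize_equal_width(y, B: int) -> BinScheme:
    """Split training traits into B equal-width bins and compute bin means.

    Intervals are left-closed/right-open except the last bin, which is
    right-closed so the maximum is included.  Bins that receive no
    training value are dropped.
    """
    y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    if B < 2:
        raise ValueError("need at least 2 bins")
    lo, hi = y.min(), y.max()
    if lo == hi:
        raise ValueError("constant trait vector cannot be discretized")
    edges = np.linspace(lo, hi, B + 1)
    width = (hi - lo) / B
    raw = np.minimum(((y - lo) / width).astype(int), B - 1)
    occupied = np.unique(raw)
    remap = {b: r for r, b in enumerate(occupied)}
    bin_of = np.asarray([remap[b] for b in raw])
    means = np.asarray([y[raw == b].mean() for b in occupied])
    return BinScheme(edges=edges, means=means, bin_of=bin_of)


class _ConstantClassifier:
    """Fallback for a cut whose one side is empty: the class prior."""

    def __init__(self, p_positive: float):
        self.p_positive = p_positive

    def predict_proba(self, X):
        n = np.asarray(getattr(X, "values", X)).shape[0]
        return np.column_stack(
            [np.full(n, 1 - self.p_positive), np.full(n, self.p_positive)]
        )

    @property
    def classes_(self):
        return np.array([0, 1])


def _positive_proba(clf, X) -> np.ndarray:
    proba = clf.predict_proba(X)
    classes = list(clf.classes_)
    if 1 not in classes:
        return np.zeros(proba.shape[0])
    return proba[:, classes.index(1)]


class McRank(BaseEstimator):
    """Pointwise ranker via discretization and expected-value scoring.

    Parameters
    ----------
    variant : {"ordinal", "multiclass"}
    n_bins : int
        Requested number of equal-width bins (>= 2); empty bins are
        dropped, so the fitted scheme may have fewer.
    classifier : estimator or None
        Probabilistic classifier template (cloned per cut / fitted once
        for multiclass).  Defaults to a 300-tree random forest with a
        0.6 feature fraction.
    random_state : int
        Seed for the default classifier.
    """

    def __init__(self, variant: str = "ordinal", n_bins: int = 10,
                 classifier=None, random_state: int = 0):
        self.variant = variant
        self.n_bins = n_bins
        self.classifier = classifier
        self.random_state = random_state

    def _template(self):
        if self.classifier is not None:
            return clone(self.classifier)
        return RandomForestClassifier(
            n_estimators=300,
            max_features=0.6,
            max_depth=5,
            random_state=self.random_state,
        )

    def fit(self, X, y):
        if self.variant not in ("ordinal", "multiclass"):
            raise ValueError(f"unknown variant {self.variant!r}")
        X = np.asarray(getattr(X, "values", X), dtype=float)
        y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of samples")
        scheme = discretize_equal_width(y, self.n_bins)
        self.scheme_ = scheme
        self.n_features_in_ = X.shape[1]
        labels = scheme.bin_of
        if self.variant == "multiclass":
            self.classifier_ = self._template().fit(X, labels)
        else:
            self.cut_classifiers_ = []
            for r in range(scheme.n_bins - 1):
                positive = labels <= r
                if positive.all() or not positive.any():
                    warnings.warn(
                        f"cut {r}: one side of the partition is empty; "
                        "using the class prior",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    self.cut_classifiers_.append(
                        _ConstantClassifier(float(positive.mean()))
                    )
                else:
                    clf = self._template().fit(X, positive.astype(int))
                    self.cut_classifiers_.append(clf)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-candidate probability over the retained bins (rows sum to 1)."""
        check_is_fitted(self, "scheme_")
        X = np.asarray(getattr(X, "values", X), dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"marker count mismatch: expected {self.n_features_in_}, "
                f"got {X.shape[1]}"
            )
        B = self.scheme_.n_bins
        if self.variant == "multiclass":
            proba = np.zeros((X.shape[0], B))
            raw = self.classifier_.predict_proba(X)
            for col, cls in enumerate(self.classifier_.classes_):
                proba[:, int(cls)] = raw[:, col]
            return proba
        # ordinal: cumulative estimates, differenced then repaired
        F = np.ones((X.shape[0], B))
        for r, clf in enumerate(self.cut_classifiers_):
            F[:, r] = _positive_proba(clf, X)
        proba = np.diff(F, axis=1, prepend=0.0)
        np.maximum(proba, 0.0, out=proba)
        proba /= proba.sum(axis=1, keepdims=True)
        return proba

    def predict(self, X) -> np.ndarray:
        """Expected trait value under the bin-probability estimates."""
        return self.predict_proba(X) @ self.scheme_.means


def fit_multiclass_mcrank(X, y, B: int, clf=None,
                          random_state: int = 0) -> McRank:
    """Functional wrapper: multiclass variant."""
    return McRank(variant="multiclass", n_bins=B, classifier=clf,
                  random_state=random_state).fit(X, y)


def fit_ordinal_mcrank(X, y, B: int, clf=None,
                       random_state: int = 0) -> McRank:
    """Functional wrapper: ordinal (cumulative-cut) variant."""
    return McRank(variant="ordinal", n_bins=B, classifier=clf,
                  random_state=random_state).fit(X, y)


def mcrank_score(model: McRank, X) -> np.ndarray:
    """Expected-trait-value scores for candidates."""
    return model.predict(X)
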