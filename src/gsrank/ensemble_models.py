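"""Tree-ensemble rankers: residual boosting (GBRT) and lambda-gradient
boosting (LambdaMART).

Both build the same staged additive model ``h(x) = h0 + sum_s w_s
h_s(x)`` over shallow regression trees; they differ only in the stage
targets.  GBRT fits each tree to the squared-loss residuals of the
ensemble so far, with an exact line-search stage weight shrunk by the
learning rate.  LambdaMART targets NDCG@k directly: since NDCG is a
discontinuous function of the scores, each stage fits the tree to the
lambda-gradient — a per-individual sum of pairwise push strengths

    lambda_ij = |DeltaNDCG_ij| * 1 / (1 + exp(s_i - s_j))

over preference pairs (y_i > y_j), where DeltaNDCG_ij is the
(normalized) NDCG@k change from swapping i and j in the current
ranking.  The preferred item of a pair is pushed up and the other down
(lambda_ji = -lambda_ij), and pairs with both items ranked below k
contribute nothing — swapping them cannot change NDCG@k.

Tree induction itself is delegated to scikit-learn's
DecisionTreeRegressor behind a small contract (max depth, random
feature-subset fraction, seed); the randomization heuristics follow
random-forest practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .metrics import (
    GainDiscountSpec,
    dcg_at_k,
    induced_permutation,
    pair_partition,
)

__all__ = [
    "TreeLearnerContract",
    "Ensemble",
    "LambdaState",
    "fit_regression_tree",
    "GradientBoostedTrees",
    "LambdaMART",
    "fit_gbrt",
    "fit_lambdamart",
    "delta_ndcg_swap",
    "lambda_gradient",
    "predict_ensemble",
]


@dataclass(frozen=True)
class TreeLearnerContract:
    """Base-tree configuration: depth cap, feature-subset fraction, seed.

    Fitting the same targets under the same seed must give identical
    predictions; any learner honoring that plus the limits below can
    serve as the base tree.
    """

    max_depth: int | None = 5
    max_features_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.max_features_fraction <= 1:
            raise ValueError("max_features_fraction must be in (0, 1]")


def fit_regression_tree(X, targets, contract: TreeLearnerContract):
    """CART-style variance-reduction tree honoring the contract limits."""
    X = np.asarray(getattr(X, "values", X), dtype=float)
    targets = np.asarray(targets, dtype=float).ravel()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    tree = DecisionTreeRegressor(
        max_depth=contract.max_depth,
        max_features=contract.max_features_fraction,
        random_state=contract.seed,
    )
    return tree.fit(X, targets)


@dataclass
class Ensemble:
    """Staged additive tree model: base value plus weighted tree outputs."""

    base_value: float
    trees: list = field(default_factory=list)
    weights: list = field(default_factory=list)
    learning_rate: float = 0.1

    def predict(self, X) -> np.ndarray:
        X = np.asarray(getattr(X, "values", X), dtype=float)
        out = np.full(X.shape[0], self.base_value, dtype=float)
        for tree, w in zip(self.trees, self.weights):
            out += w * tree.predict(X)
        return out


def predict_ensemble(model, X) -> np.ndarray:
    """Base value plus weighted stage sums for a fitted ensemble."""
    ensemble = getattr(model, "ensemble_", model)
    expected_p = getattr(model, "n_features_in_", None)
    X = np.asarray(getattr(X, "values", X), dtype=float)
    if expected_p is not None and X.shape[1] != expected_p:
        raise ValueError(
            f"marker count mismatch: expected {expected_p}, got {X.shape[1]}"
        )
    return ensemble.predict(X)


@dataclass(frozen=True)
class LambdaState:
    """Lambda-gradient vector at the current scores, for NDCG@k."""

    position_k: int
    lambda_vector: np.ndarray


def _discounts_topk(ranks: np.ndarray, k: int,
                    spec: GainDiscountSpec) -> np.ndarray:
    """Per-item discount at its rank, zero beyond position k."""
    d = np.zeros(len(ranks))
    inside = ranks <= k
    if spec.discount == "log2":
        d[inside] = 1.0 / np.log2(ranks[inside] + 1)
    else:
        d[inside] = 1.0
    return d


def _ideal_dcg(y: np.ndarray, k: int, spec: GainDiscountSpec) -> float:
    return dcg_at_k(y, induced_permutation(y), k, spec)


def delta_ndcg_swap(y, perm, i: int, j: int, k: int,
                    spec: GainDiscountSpec | None = None) -> float:
    """|NDCG@k change| from swapping the ranks of items i and j.

    Exactly zero when both items rank below k or their gains are equal.
    Only the two swapped positions change, so the difference reduces to
    ``|(g_i - g_j) (d(rank_i) - d(rank_j))| / idealDCG`` with the
    discount zeroed beyond position k.
    """
    y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    perm = np.asarray(perm)
    spec = spec or GainDiscountSpec()
    if not 1 <= k <= len(y):
        raise ValueError(f"k={k} outside 1..{len(y)}")
    if i == j:
        raise ValueError("need two distinct items")
    ranks = np.empty(len(y), dtype=int)
    ranks[perm] = np.arange(1, len(y) + 1)
    d = _discounts_topk(ranks[[i, j]], k, spec)
    g = spec.gains(y[[i, j]])
    ideal = _ideal_dcg(y, k, spec)
    if ideal == 0:
        return 0.0
    return abs((g[0] - g[1]) * (d[0] - d[1])) / ideal


def lambda_gradient(y, s, k: int,
                    spec: GainDiscountSpec | None = None) -> LambdaState:
    """Lambda-gradient of NDCG@k at scores s.

    For every preference pair (i, j) with y_i > y_j the preferred item
    i receives an upward push and j the matching downward push of
    strength |DeltaNDCG_ij| / (1 + exp(s_i - s_j)); per-item lambdas
    sum the pushes.  Antisymmetry makes the vector sum to zero.
    """
    y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    s = np.asarray(getattr(s, "values", s), dtype=float).ravel()
    spec = spec or GainDiscountSpec()
    part = pair_partition(y, s)
    if part.n_pairs == 0:
        raise ValueError("constant trait vector: no preference pairs")
    perm = induced_permutation(s)
    ranks = np.empty(len(y), dtype=int)
    ranks[perm] = np.arange(1, len(y) + 1)
    d = _discounts_topk(ranks, k, spec)
    g = spec.gains(y)
    ideal = _ideal_dcg(y, k, spec)
    lam = np.zeros(len(y))
    if ideal > 0:
        i, j = part.preference[:, 0], part.preference[:, 1]
        delta = np.abs((g[i] - g[j]) * (d[i] - d[j])) / ideal
        push = delta * expit(-(s[i] - s[j]))
        np.add.at(lam, i, push)
        np.subtract.at(lam, j, push)
    return LambdaState(position_k=k, lambda_vector=lam)


class _StagedTreeBooster(RegressorMixin, BaseEstimator):
    """Shared machinery for staged tree boosting."""

    def __init__(self, n_estimators=300, learning_rate=0.1, max_depth=5,
                 max_features=0.6, random_state=0):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.max_features = max_features
        self.random_state = random_state

    def _validate(self, X, y):
        X = np.asarray(getattr(X, "values", X), dtype=float)
        y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of samples")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if self.n_estimators < 0:
            raise ValueError("n_estimators must be >= 0")
        return X, y

    def _stage_tree(self, X, targets, seed):
        contract = TreeLearnerContract(
            max_depth=self.max_depth,
            max_features_fraction=self.max_features,
            seed=seed,
        )
        return fit_regression_tree(X, targets, contract)

    def predict(self, X):
        check_is_fitted(self, "ensemble_")
        return predict_ensemble(self, X)


class GradientBoostedTrees(_StagedTreeBooster):
    """Gradient-boosted regression trees for squared loss.

    Starts from the training-mean base model; each stage fits a tree to
    the current residuals and weights it by an exact line search for
    squared loss, shrunk by the learning rate.  Training MSE is
    non-increasing stage to stage.
    """

    def fit(self, X, y):
        X, y = self._validate(X, y)
        rng = np.random.default_rng(self.random_state)
        ens = Ensemble(base_value=float(y.mean()),
                       learning_rate=self.learning_rate)
        pred = np.full(len(y), ens.base_value)
        mse_path = [float(np.mean((y - pred) ** 2))]
        for _ in range(self.n_estimators):
            resid = y - pred
            tree = self._stage_tree(X, resid, int(rng.integers(2 ** 31)))
            t = tree.predict(X)
            tt = float(t @ t)
            # exact line search for squared loss, then shrink
            alpha = float(resid @ t) / tt if tt > 0 else 0.0
            w = self.learning_rate * alpha
            ens.trees.append(tree)
            ens.weights.append(w)
            pred = pred + w * t
            mse_path.append(float(np.mean((y - pred) ** 2)))
        self.ensemble_ = ens
        self.train_mse_path_ = np.asarray(mse_path)
        self.n_features_in_ = X.shape[1]
        return self


class LambdaMART(_StagedTreeBooster):
    """Listwise boosting of NDCG@k via lambda-gradients.

    Each stage fits a tree to the lambda-gradient at the current scores
    and adds it with weight equal to the learning rate — the lambda
    surrogate has no primitive objective to line-search.  Scores are
    ranking scores, not trait predictions; the base value is zero.
    """

    def __init__(self, k=10, n_estimators=300, learning_rate=0.1,
                 max_depth=5, max_features=0.6, random_state=0):
        super().__init__(n_estimators, learning_rate, max_depth,
                         max_features, random_state)
        self.k = k

    def fit(self, X, y):
        X, y = self._validate(X, y)
        if y.min() < 0:
            raise ValueError(
                "LambdaMART optimizes NDCG and needs nonnegative traits; "
                "apply gsrank.data_io.shift_nonnegative first"
            )
        k = min(self.k, len(y))
        rng = np.random.default_rng(self.random_state)
        ens = Ensemble(base_value=0.0, learning_rate=self.learning_rate)
        scores = np.zeros(len(y))
        for _ in range(self.n_estimators):
            lam = lambda_gradient(y, scores, k).lambda_vector
            tree = self._stage_tree(X, lam, int(rng.integers(2 ** 31)))
            ens.trees.append(tree)
            ens.weights.append(self.learning_rate)
            scores = scores + self.learning_rate * tree.predict(X)
        self.ensemble_ = ens
        self.n_features_in_ = X.shape[1]
        return self


def fit_gbrt(X, y, M: int, lr: float,
             contract: TreeLearnerContract | None = None) -> GradientBoostedTrees:
    """Functional wrapper over :class:`GradientBoostedTrees`."""
    contract = contract or TreeLearnerContract()
    model = GradientBoostedTrees(
        n_estimators=M,
        learning_rate=lr,
        max_depth=contract.max_depth,
        max_features=contract.max_features_fraction,
        random_state=contract.seed,
    )
    return model.fit(X, y)


def fit_lambdamart(X, y, k: int, M: int, lr: float,
                   contract: TreeLearnerContract | None = None) -> LambdaMART:
    """Functional wrapper over :class:`LambdaMART`."""
    contract = contract or TreeLearnerContract()
    model = LambdaMART(
        k=k,
        n_estimators=M,
        learning_rate=lr,
        max_depth=contract.max_depth,
        max_features=contract.max_features_fraction,
        random_state=contract.seed,
    )
    return model.fit(X, y)
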