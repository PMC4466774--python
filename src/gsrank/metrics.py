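"""Evaluation measures for regression- and ranking-based genomic selection.

Two families are implemented.  Global measures treat every individual
equally: mean squared error, Pearson correlation, and the pair-based
measures (pairwise accuracy, Kendall's tau) built on the strict
preference set ``P(y) = {(i, j) : y_i > y_j}``.  Top-k measures weight
the head of the ranking: DCG@k, its normalized form NDCG@k, and Mean
NDCG@K, the mean of NDCG@k over k = 1..K.  Spearman's rho is provided
for measure-agreement analysis.

Conventions that matter:

* Kendall's tau is computed exactly as ``(|C| - |D|) / |P(y)|`` over the
  strict preference set.  On a tie-free reference this is the classical
  tau-a and satisfies ``tau = 2 * pairwise_accuracy - 1``; it is
  deliberately *not* the tie-corrected tau-b that general statistics
  routines return, so values can differ from those on tied data.
* Score ties in the induced permutation are broken by ascending original
  index (stable), so every measure is deterministic.
* NDCG requires nonnegative gains; negative traits raise and point the
  caller at :func:`gsrank.data_io.shift_nonnegative`.  An all-zero
  reference (ideal DCG of zero) yields NDCG 0 with a warning instead of
  a crash, so batch cross-validation survives degenerate folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "GainDiscountSpec",
    "PairPartition",
    "mse",
    "pearson",
    "pair_partition",
    "pairwise_accuracy",
    "kendall_tau",
    "induced_permutation",
    "dcg_at_k",
    "ndcg_at_k",
    "mean_ndcg_at_k",
    "spearman_rho",
    "evaluate",
    "HIGHER_IS_BETTER",
]


def _as1d(x) -> np.ndarray:
    values = getattr(x, "values", x)
    return np.asarray(values, dtype=float).ravel()


def _check_lengths(y: np.ndarray, s: np.ndarray) -> None:
    if len(y) != len(s):
        raise ValueError(f"length mismatch: {len(y)} vs {len(s)}")


@dataclass(frozen=True)
class GainDiscountSpec:
    """Gain/discount choices for DCG-family measures.

    Defaults are linear gain g(y) = y (trait values are not bounded
    relevance grades, so exponential gain can explode) and the standard
    logarithmic discount d(i) = 1/log2(i + 1).  ``discount="none"``
    (d(i) = 1) ignores order within the top k.
    """

    gain: str = "linear"
    discount: str = "log2"

    def __post_init__(self) -> None:
        if self.gain not in ("linear", "exponential"):
            raise ValueError(f"unknown gain {self.gain!r}")
        if self.discount not in ("log2", "none"):
            raise ValueError(f"unknown discount {self.discount!r}")

    def gains(self, y: np.ndarray) -> np.ndarray:
        if self.gain == "linear":
            return y
        return np.exp2(y) - 1.0

    def discounts(self, k: int) -> np.ndarray:
        ranks = np.arange(1, k + 1)
        if self.discount == "log2":
            return 1.0 / np.log2(ranks + 1)
        return np.ones(k)


@dataclass(frozen=True)
class PairPartition:
    """The preference set P(y) split against predicted scores.

    ``preference`` holds ordered pairs (i, j) with y_i > y_j;
    ``concordant``/``discordant``/``tied`` partition it by whether the
    scores order the pair correctly, incorrectly, or not at all.
    """

    preference: np.ndarray   # (m, 2) int array
    concordant: np.ndarray
    discordant: np.ndarray
    tied: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.preference)


def mse(y, s) -> float:
    """Mean squared error; zero iff the prediction is exact."""
    y, s = _as1d(y), _as1d(s)
    _check_lengths(y, s)
    if len(y) == 0:
        raise ValueError("empty input")
    return float(np.mean((y - s) ** 2))


def pearson(y, s) -> float:
    """Pearson product-moment correlation of observed vs predicted values."""
    y, s = _as1d(y), _as1d(s)
    _check_lengths(y, s)
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    yc, sc = y - y.mean(), s - s.mean()
    denom = np.sqrt((yc ** 2).sum() * (sc ** 2).sum())
    if denom == 0:
        raise ValueError("constant input: Pearson correlation undefined")
    return float(np.clip((yc * sc).sum() / denom, -1.0, 1.0))


def pair_partition(y, s) -> PairPartition:
    """Enumerate P(y) and split it into concordant/discordant/tied pairs."""
    y, s = _as1d(y), _as1d(s)
    _check_lengths(y, s)
    i, j = np.nonzero(y[:, None] > y[None, :])
    pairs = np.column_stack([i, j])
    si, sj = s[i], s[j]
    return PairPartition(
        preference=pairs,
        concordant=pairs[si > sj],
        discordant=pairs[si < sj],
        tied=pairs[si == sj],
    )


def _require_pairs(part: PairPartition) -> None:
    if part.n_pairs == 0:
        raise ValueError(
            "constant reference trait: the preference set is empty and "
            "pair-based measures are undefined"
        )


def pairwise_accuracy(y, s) -> float:
    """Proportion of preference pairs the scores order correctly (in [0, 1])."""
    part = pair_partition(y, s)
    _require_pairs(part)
    return len(part.concordant) / part.n_pairs


def kendall_tau(y, s) -> float:
    """(|C| - |D|) / |P(y)|: concordant minus discordant pair ratio."""
    part = pair_partition(y, s)
    _require_pairs(part)
    return (len(part.concordant) - len(part.discordant)) / part.n_pairs


def induced_permutation(s) -> np.ndarray:
    """0-based index order sorting scores decreasingly, ties by index."""
    s = _as1d(s)
    if len(s) == 0:
        raise ValueError("empty score vector")
    return np.argsort(-s, kind="stable")


def dcg_at_k(y, perm, k: int, spec: GainDiscountSpec | None = None) -> float:
    """Discounted cumulative gain of ``perm`` at position k."""
    y = _as1d(y)
    perm = np.asarray(perm)
    spec = spec or GainDiscountSpec()
    if not 1 <= k <= len(y):
        raise ValueError(f"k={k} outside 1..{len(y)}")
    gains = spec.gains(y[perm[:k]])
    return float(gains @ spec.discounts(k))


def ndcg_at_k(y, s, k: int, spec: GainDiscountSpec | None = None) -> float:
    """DCG of the predicted ranking over DCG of the ideal ranking.

    In [0, 1] for nonnegative traits; 1 whenever the scores order the
    top k non-increasingly in y.
    """
    y, s = _as1d(y), _as1d(s)
    _check_lengths(y, s)
    spec = spec or GainDiscountSpec()
    if y.min() < 0:
        raise ValueError(
            "NDCG requires nonnegative trait values; apply "
            "gsrank.data_io.shift_nonnegative first"
        )
    ideal = dcg_at_k(y, induced_permutation(y), k, spec)
    if ideal == 0:
        warnings.warn(
            "ideal DCG is zero (all top-k gains zero); NDCG defined as 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return dcg_at_k(y, induced_permutation(s), k, spec) / ideal


def mean_ndcg_at_k(y, s, K: int, spec: GainDiscountSpec | None = None) -> float:
    """Mean of NDCG@k over k = 1..K."""
    y = _as1d(y)
    if not 1 <= K <= len(y):
        raise ValueError(f"K={K} outside 1..{len(y)}")
    return float(np.mean([ndcg_at_k(y, s, k, spec) for k in range(1, K + 1)]))


def spearman_rho(a, b) -> float:
    """Pearson correlation of average-rank-transformed vectors."""
    a, b = _as1d(a), _as1d(b)
    _check_lengths(a, b)
    return pearson(rankdata(a), rankdata(b))


#: Direction of each measure for model selection (False = minimize).
HIGHER_IS_BETTER = {
    "mse": False,
    "pearson": True,
    "tau": True,
    "pa": True,
}


def _parse_at(name: str, prefix: str) -> int | None:
    if name.startswith(prefix):
        try:
            return int(name[len(prefix):])
        except ValueError:
            return None
    return None


def evaluate(y, s, measures, spec: GainDiscountSpec | None = None) -> dict:
    """Compute a named set of measures; names like ``ndcg@5``, ``tau``, ``mse``.

    Recognized names: ``mse``, ``pearson``, ``tau``, ``pa``, ``ndcg@K``
    and ``mean-ndcg@K``.
    """
    out: dict[str, float] = {}
    for name in measures:
        key = name.strip().lower()
        if key == "mse":
            out[name] = mse(y, s)
        elif key == "pearson":
            out[name] = pearson(y, s)
        elif key in ("tau", "kendall", "kendalltau"):
            out[name] = kendall_tau(y, s)
        elif key in ("pa", "pairwise-accuracy", "pairwiseaccuracy"):
            out[name] = pairwise_accuracy(y, s)
        elif (k := _parse_at(key, "ndcg@")) is not None:
            out[name] = ndcg_at_k(y, s, k, spec)
        elif (k := _parse_at(key, "mean-ndcg@")) is not None:
            out[name] = mean_ndcg_at_k(y, s, k, spec)
        else:
            raise ValueError(f"unknown measure {name!r}")
    return out


def measure_higher_is_better(name: str) -> bool:
    key = name.strip().lower()
    if key in HIGHER_IS_BETTER:
        return HIGHER_IS_BETTER[key]
    if key.startswith(("ndcg@", "mean-ndcg@")):
        return True
    raise ValueError(f"unknown measure {name!r}")
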