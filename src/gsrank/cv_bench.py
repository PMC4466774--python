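"""Benchmarking protocol: randomized 80/20 cross-validation with nested
measure-targeted hyper-parameter tuning.

The protocol mirrors common genomic-selection practice: for each of 10
outer iterations the data are split at random into 80% for model
estimation and 20% for evaluation, every method sees the identical
split, and methods with tunable hyper-parameters pick them by 5-fold
cross-validation *within* the training split, maximizing the very
measure used for evaluation (minimizing for MSE).  Scores are averaged
over iterations, and over traits when a dataset carries several.

Two summaries across datasets reproduce the usual report shapes:
``rank_methods`` ranks methods within each dataset per measure (1 =
best, average ranks on ties) and averages ranks across datasets;
``measure_agreement`` correlates measures with each other via
Spearman's rho over the per-method mean scores, averaged across
datasets.

Everything is deterministic given the master seed: the split sequence
is a function of (n, seed, iteration) only, so adding or removing a
method never changes the splits.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone

from .data_io import Dataset
from .metrics import evaluate, measure_higher_is_better, spearman_rho

logger = logging.getLogger(__name__)

__all__ = [
    "CVConfig",
    "BenchmarkResult",
    "random_split",
    "expand_grid",
    "inner_tune",
    "run_benchmark",
    "rank_methods",
    "measure_agreement",
    "DEFAULT_GRIDS",
]

#: Hyper-parameter grids used in the benchmarking protocol.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "ranksvm": {"lam_tilde": np.logspace(-6, 6, 15).tolist()},
    "rkhs": {"lam": np.logspace(-6, 6, 15).tolist()},
    "sigma": {"sigma": np.linspace(0.1, 1.0, 10).tolist()},
    "trees": {"max_depth": [3, 5, 10]},
    "boosting": {"learning_rate": [0.001, 0.01, 0.1, 1.0],
                 "max_depth": [3, 5, 10]},
    "mcrank": {"n_bins": list(range(3, 21)), "max_depth": [3, 5, 10]},
}


@dataclass(frozen=True)
class CVConfig:
    """Protocol parameters: 80/20 splits, 10 iterations, 5 inner folds."""

    train_fraction: float = 0.8
    outer_iterations: int = 10
    inner_folds: int = 5
    tuning_measure: str = "mean-ndcg@10"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.outer_iterations < 1:
            raise ValueError("outer_iterations must be >= 1")
        if self.inner_folds < 2:
            raise ValueError("inner_folds must be >= 2")


def random_split(n: int, fraction: float, seed: int,
                 iteration: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic random train/test split.

    The split is a function of (n, seed, iteration) only, so every
    method evaluated under the same configuration sees the same splits.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng([n, seed, iteration])
    perm = rng.permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def expand_grid(grid: dict[str, list]) -> list[dict]:
    """All grid points in deterministic (insertion) order."""
    if not grid:
        return [{}]
    keys = list(grid)
    for k in keys:
        if not grid[k]:
            raise ValueError(f"empty value list for grid parameter {k!r}")
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def _kfold_indices(n: int, folds: int, seed: int):
    rng = np.random.default_rng([n, seed, 97])
    perm = rng.permutation(n)
    for part in np.array_split(perm, folds):
        val = np.sort(part)
        train = np.sort(np.setdiff1d(perm, part))
        yield train, val


def inner_tune(estimator, grid: dict[str, list], X, y, folds: int,
               measure: str, seed: int) -> dict:
    """Pick the grid point maximizing the mean inner-fold measure.

    MSE is minimized; every other measure is maximized.  Ties break to
    the earlier grid point.  A grid point whose fit fails anywhere is
    scored as worst and logged.
    """
    points = expand_grid(grid)
    if len(points) == 1:
        return points[0]
    X = np.asarray(getattr(X, "values", X), dtype=float)
    y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    higher = measure_higher_is_better(measure)
    best_point, best_score = points[0], -np.inf
    folds_idx = list(_kfold_indices(len(y), folds, seed))
    for point in points:
        scores = []
        try:
            for tr, val in folds_idx:
                model = clone(estimator).set_params(**point)
                model.fit(X[tr], y[tr])
                s = model.predict(X[val])
                scores.append(evaluate(y[val], s, [measure])[measure])
            mean_score = float(np.mean(scores))
        except Exception as exc:  # noqa: BLE001 - any failure scores worst
            logger.warning("inner_tune: grid point %r failed: %s", point, exc)
            mean_score = -np.inf if higher else np.inf
        value = mean_score if higher else -mean_score
        if value > best_score:
            best_point, best_score = point, value
    return best_point


@dataclass
class BenchmarkResult:
    """Per-iteration scores plus the hyper-parameters chosen per split."""

    scores: pd.DataFrame  # columns: method, trait, measure, iteration, value
    chosen_params: pd.DataFrame
    dataset_name: str = "dataset"

    def summary(self) -> pd.DataFrame:
        """Mean score per (method, measure), averaged over traits and
        iterations; 3-decimal table in report form."""
        table = (
            self.scores.groupby(["method", "measure"])["value"]
            .mean()
            .unstack("measure")
        )
        return table.round(3)

    def method_means(self) -> pd.DataFrame:
        return (
            self.scores.groupby(["method", "measure"])["value"]
            .mean()
            .unstack("measure")
        )


def run_benchmark(data: Dataset, methods: dict, measures: list[str],
                  cfg: CVConfig,
                  grids: dict[str, dict] | None = None,
                  name: str = "dataset") -> BenchmarkResult:
    """Run the full protocol for every method and measure.

    ``methods`` maps a method name to an (unfitted) estimator; ``grids``
    optionally maps the same names to hyper-parameter grids for nested
    tuning (absent or singleton grids skip the inner loop).  Traits are
    evaluated separately and all appear in the score table; summaries
    average across them.  A method failing on a split is recorded as
    missing and excluded from averages.
    """
    grids = grids or {}
    X = data.markers.values.astype(float)
    n = X.shape[0]
    rows, param_rows = [], []
    for it in range(cfg.outer_iterations):
        train, test = random_split(n, cfg.train_fraction, cfg.seed, it)
        for trait in data.traits:
            y = trait.values
            for mname, estimator in methods.items():
                grid = grids.get(mname, {})
                try:
                    params = inner_tune(
                        estimator, grid, X[train], y[train],
                        cfg.inner_folds, cfg.tuning_measure, cfg.seed,
                    )
                    model = clone(estimator).set_params(**params)
                    model.fit(X[train], y[train])
                    s = model.predict(X[test])
                    vals = evaluate(y[test], s, measures)
                except Exception as exc:  # noqa: BLE001
                    warnings.warn(
                        f"method {mname!r} failed on iteration {it} "
                        f"(trait {trait.trait_name!r}): {exc}",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    vals = {m: np.nan for m in measures}
                    params = {}
                param_rows.append(
                    {"method": mname, "trait": trait.trait_name,
                     "iteration": it, **params}
                )
                for measure, value in vals.items():
                    rows.append(
                        {"method": mname, "trait": trait.trait_name,
                         "measure": measure, "iteration": it,
                         "value": value}
                    )
    return BenchmarkResult(
        scores=pd.DataFrame(rows),
        chosen_params=pd.DataFrame(param_rows),
        dataset_name=name,
    )


def rank_methods(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Rank methods per measure within each dataset and average the ranks.

    Rank 1 is best (highest score; lowest for MSE); tied methods share
    the average rank.  Output rows are sorted by the mean of the
    average ranks across measures.
    """
    methods = None
    for res in results:
        present = set(res.scores["method"].unique())
        if methods is None:
            methods = present
        elif present != methods:
            raise ValueError("all results must cover the same methods")
    per_dataset = []
    for res in results:
        means = res.method_means()
        ranks = {}
        for measure in means.columns:
            col = means[measure]
            sign = 1.0 if measure_higher_is_better(measure) else -1.0
            ranks[measure] = pd.Series(
                rankdata(-sign * col.to_numpy(), method="average"),
                index=col.index,
            )
        per_dataset.append(pd.DataFrame(ranks))
    avg = sum(per_dataset) / len(per_dataset)
    return avg.loc[avg.mean(axis=1).sort_values(kind="stable").index]


def measure_agreement(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Spearman's rho between measures over per-method mean scores.

    Computed per dataset and averaged across datasets; symmetric with a
    unit diagonal.  Needs at least 3 methods for ranks to be
    informative.
    """
    mats = []
    for res in results:
        means = res.method_means()
        if means.shape[0] < 3:
            raise ValueError("need at least 3 methods for measure agreement")
        measures = list(means.columns)
        m = pd.DataFrame(np.eye(len(measures)), index=measures,
                         columns=measures)
        for a, b in itertools.combinations(measures, 2):
            rho = spearman_rho(means[a].to_numpy(), means[b].to_numpy())
            m.loc[a, b] = m.loc[b, a] = rho
        mats.append(m)
    return sum(mats) / len(mats)
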