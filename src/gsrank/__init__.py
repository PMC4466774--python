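"""gsrank: ranking-based genomic selection.

Selective breeding needs the *best* candidates, not accurate trait
predictions for everyone.  This package treats genomic selection as a
learning-to-rank problem: it provides top-k ranking measures (DCG,
NDCG@k, Mean NDCG@K) alongside global ones (Pearson r, Kendall's tau,
pairwise accuracy), rankers from the three learning-to-rank families
(ordinal/multiclass McRank, kernel RankSVM, LambdaMART) next to
regression baselines (RKHS/kernel ridge, gradient-boosted trees), a
randomized cross-validation benchmarking protocol with nested
measure-targeted tuning, and a genotype/trait simulator with known
ground truth.

All learners are scikit-learn-style estimators and compose with
sklearn pipelines and model selection.
"""

from .data_io import (
    Dataset,
    MarkerMatrix,
    TraitVector,
    align,
    read_marker_matrix,
    read_traits,
    shift_nonnegative,
    write_marker_matrix,
    write_traits,
)
from .metrics import (
    GainDiscountSpec,
    dcg_at_k,
    evaluate,
    induced_permutation,
    kendall_tau,
    mean_ndcg_at_k,
    mse,
    ndcg_at_k,
    pair_partition,
    pairwise_accuracy,
    pearson,
    spearman_rho,
)
from .kernel_models import (
    KernelSpec,
    RankSVM,
    RKHSRegressor,
    compute_kernel,
    gamma_from_sigma,
)
from .ensemble_models import (
    GradientBoostedTrees,
    LambdaMART,
    TreeLearnerContract,
    delta_ndcg_swap,
    lambda_gradient,
)
from .mcrank import BinScheme, McRank, discretize_equal_width
from .cv_bench import (
    CVConfig,
    BenchmarkResult,
    inner_tune,
    measure_agreement,
    random_split,
    rank_methods,
    run_benchmark,
)
from .synthetic import SimConfig, SimulatedDataset, simulate_dataset

__version__ = "0.1.0"

__all__ = [
    "Dataset", "MarkerMatrix", "TraitVector", "align",
    "read_marker_matrix", "read_traits", "shift_nonnegative",
    "write_marker_matrix", "write_traits",
    "GainDiscountSpec", "dcg_at_k", "evaluate", "induced_permutation",
    "kendall_tau", "mean_ndcg_at_k", "mse", "ndcg_at_k", "pair_partition",
    "pairwise_accuracy", "pearson", "spearman_rho",
    "KernelSpec", "RankSVM", "RKHSRegressor", "compute_kernel",
    "gamma_from_sigma",
    "GradientBoostedTrees", "LambdaMART", "TreeLearnerContract",
    "delta_ndcg_swap", "lambda_gradient",
    "BinScheme", "McRank", "discretize_equal_width",
    "CVConfig", "BenchmarkResult", "inner_tune", "measure_agreement",
    "random_split", "rank_methods", "run_benchmark",
    "SimConfig", "SimulatedDataset", "simulate_dataset",
    "make_method",
]


def make_method(name: str, seed: int = 0, **overrides):
    """Build a ranking/regression estimator by its benchmark name.

    Recognized names: ``rkhs``, ``rkhs-rbf``, ``ranksvm``,
    ``ranksvm-rbf``, ``gbrt``, ``lambdamart``, ``rf``,
    ``mcrank-ordinal``, ``mcrank-multiclass``.
    """
    from sklearn.ensemble import RandomForestRegressor

    builders = {
        "rkhs": lambda: RKHSRegressor(kernel="linear"),
        "rkhs-rbf": lambda: RKHSRegressor(kernel="rbf"),
        "ranksvm": lambda: RankSVM(kernel="linear"),
        "ranksvm-rbf": lambda: RankSVM(kernel="rbf"),
        "gbrt": lambda: GradientBoostedTrees(random_state=seed),
        "lambdamart": lambda: LambdaMART(random_state=seed),
        "rf": lambda: RandomForestRegressor(
            n_estimators=300, max_features=0.6, max_depth=5,
            random_state=seed,
        ),
        "mcrank-ordinal": lambda: McRank(variant="ordinal",
                                         random_state=seed),
        "mcrank-multiclass": lambda: McRank(variant="multiclass",
                                            random_state=seed),
    }
    key = name.strip().lower()
    if key not in builders:
        raise ValueError(
            f"unknown method {name!r}; choose from {sorted(builders)}"
        )
    est = builders[key]()
    if overrides:
        est.set_params(**overrides)
    return est
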