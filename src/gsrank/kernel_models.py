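"""Kernel machines in the dual: RKHS/kernel ridge regression and RankSVM.

Both models share one representation: a dual coefficient vector alpha
over the n training individuals, with scores ``h(x) = sum_i alpha_i
kappa(x, x_i)``.  Working in the dual means solving an n-dimensional
problem instead of a p-dimensional one, which is the right trade in the
n << p regime of genomic selection.

Kernel ridge solves ``(K + lambda I) alpha = y`` in closed form; with a
linear kernel it is exactly primal ridge regression / GBLUP.  RankSVM
minimizes the squared-hinge pairwise objective

    f(alpha) = (lambda/2) alpha' K alpha
               + sum_{(i,j) in P(y)} max(0, 1 - alpha'K_i + alpha'K_j)^2

over the strict preference set P(y), with ``lambda = |P(y)| *
lam_tilde`` so regularization scales with the number of pair terms.
The objective is differentiable and strictly convex, so L-BFGS-B from
alpha = 0 finds the unique global minimum.

For the RBF kernel ``kappa(a, b) = exp(-gamma ||a - b||^2)`` the width
is parameterized through sigma as ``gamma = 1 / (4 p sigma^2)``, which
keeps the useful sigma range roughly within (0, 1] regardless of the
marker count p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, optimize
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .metrics import pair_partition

__all__ = [
    "KernelSpec",
    "gamma_from_sigma",
    "compute_kernel",
    "RKHSRegressor",
    "RankSVM",
    "fit_kernel_ridge",
    "predict_dual",
    "ranksvm_objective",
    "ranksvm_gradient",
    "fit_ranksvm",
]


def gamma_from_sigma(sigma: float, p: int) -> float:
    """RBF width gamma = 1 / (4 p sigma^2)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if p < 1:
        raise ValueError(f"marker count must be >= 1, got {p}")
    return 1.0 / (4.0 * p * sigma ** 2)


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice: ``linear`` (K = A B') or ``rbf`` with width sigma."""

    kind: str = "linear"
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kind!r}")
        if self.kind == "rbf":
            if self.sigma is None or self.sigma <= 0:
                raise ValueError("rbf kernel requires sigma > 0")

    def gamma(self, p: int) -> float:
        if self.kind != "rbf":
            raise ValueError("gamma only defined for the rbf kernel")
        return gamma_from_sigma(self.sigma, p)


def _as2d(X) -> np.ndarray:
    values = getattr(X, "values", X)
    return np.asarray(values, dtype=float)


def compute_kernel(A, B, spec: KernelSpec) -> np.ndarray:
    """Kernel matrix between the rows of A (n_a x p) and B (n_b x p)."""
    A, B = _as2d(A), _as2d(B)
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"marker count mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    if spec.kind == "linear":
        return A @ B.T
    gamma = spec.gamma(A.shape[1])
    sq = (
        (A ** 2).sum(axis=1)[:, None]
        - 2.0 * (A @ B.T)
        + (B ** 2).sum(axis=1)[None, :]
    )
    np.maximum(sq, 0.0, out=sq)
    return np.exp(-gamma * sq)


class RKHSRegressor(RegressorMixin, BaseEstimator):
    """Kernel ridge (RKHS) regression in the dual.

    Parameters
    ----------
    The trait is centered before the dual solve and the training mean
    added back at prediction — the fixed population-mean effect of a
    mixed model.  Without it the regularizer would shrink the overall
    trait level toward zero, which matters for traits shifted
    nonnegative.

    Parameters
    ----------
    kernel : {"linear", "rbf"}
    sigma : float
        RBF width parameter; gamma is derived as 1/(4 p sigma^2).
        Ignored for the linear kernel.
    lam : float
        Ridge regularization lambda > 0.
    """

    def __init__(self, kernel: str = "linear", sigma: float = 0.5,
                 lam: float = 1.0):
        self.kernel = kernel
        self.sigma = sigma
        self.lam = lam

    def _spec(self) -> KernelSpec:
        return KernelSpec(
            self.kernel, self.sigma if self.kernel == "rbf" else None
        )

    def fit(self, X, y):
        X = _as2d(X)
        y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of samples")
        if self.lam <= 0:
            raise ValueError("lam must be positive")
        K = compute_kernel(X, X, self._spec())
        self.X_ = X
        self.intercept_ = float(y.mean())
        self.alpha_ = _solve_ridge(K, y - self.intercept_, self.lam)
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        K_cross = compute_kernel(_as2d(X), self.X_, self._spec())
        return self.intercept_ + K_cross @ self.alpha_


def _solve_ridge(K: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    if K.shape[0] != K.shape[1]:
        raise ValueError(f"kernel matrix must be square, got {K.shape}")
    n = K.shape[0]
    A = K + lam * np.eye(n)
    alpha = linalg.solve(A, y, assume_a="sym")
    resid = np.linalg.norm(A @ alpha - y)
    if resid > 1e-8 * max(np.linalg.norm(y), 1.0):
        # fall back to least squares on a numerically singular system
        alpha = np.linalg.lstsq(A, y, rcond=None)[0]
    return alpha


def fit_kernel_ridge(K, y, lam: float) -> np.ndarray:
    """Solve (K + lam I) alpha = y for a precomputed square kernel."""
    K = np.asarray(K, dtype=float)
    y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    if lam <= 0:
        raise ValueError("lam must be positive")
    return _solve_ridge(K, y, lam)


def predict_dual(alpha, K_cross) -> np.ndarray:
    """Scores of candidates from a cross-kernel (m x n) and dual coefficients."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    K_cross = np.asarray(K_cross, dtype=float)
    if K_cross.shape[1] != len(alpha):
        raise ValueError(
            f"cross-kernel has {K_cross.shape[1]} columns but alpha has "
            f"length {len(alpha)}"
        )
    return K_cross @ alpha


def _pair_arrays(P) -> tuple[np.ndarray, np.ndarray]:
    pairs = P.preference if hasattr(P, "preference") else np.asarray(P)
    if len(pairs) == 0:
        raise ValueError("empty preference set")
    pairs = np.asarray(pairs)
    return pairs[:, 0], pairs[:, 1]


def ranksvm_objective(alpha, K, P, lam: float) -> float:
    """Squared-hinge RankSVM objective value at alpha."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    K = np.asarray(K, dtype=float)
    i, j = _pair_arrays(P)
    s = K @ alpha
    margins = np.maximum(0.0, 1.0 - s[i] + s[j])
    return float(0.5 * lam * alpha @ s + (margins ** 2).sum())


def ranksvm_gradient(alpha, K, P, lam: float) -> np.ndarray:
    """Gradient lam*K*alpha + 2 sum max(0, 1 - s_i + s_j) (K_j - K_i)."""
    alpha = np.asarray(alpha, dtype=float).ravel()
    K = np.asarray(K, dtype=float)
    i, j = _pair_arrays(P)
    s = K @ alpha
    margins = np.maximum(0.0, 1.0 - s[i] + s[j])
    # accumulate pair weights per sample, then one kernel product
    w = np.zeros(len(alpha))
    np.add.at(w, j, margins)
    np.subtract.at(w, i, margins)
    return lam * s + 2.0 * (K @ w)


class RankSVM(BaseEstimator):
    """Kernelized pairwise RankSVM with squared hinge loss.

    ``fit`` minimizes the strictly convex dual objective with L-BFGS-B
    starting from alpha = 0; ``predict`` returns ranking scores (not
    trait-value predictions).

    Parameters
    ----------
    kernel : {"linear", "rbf"}
    sigma : float
        RBF width (gamma = 1/(4 p sigma^2)); ignored for linear.
    lam_tilde : float
        Per-pair regularization; the effective lambda is |P(y)| * lam_tilde.
    max_iter : int
        L-BFGS iteration cap (default 500).
    tol : float
        Gradient infinity-norm tolerance, scaled by n at fit time.
    """

    def __init__(self, kernel: str = "linear", sigma: float = 0.5,
                 lam_tilde: float = 1e-3, max_iter: int = 500,
                 tol: float = 1e-5):
        self.kernel = kernel
        self.sigma = sigma
        self.lam_tilde = lam_tilde
        self.max_iter = max_iter
        self.tol = tol

    def _spec(self) -> KernelSpec:
        return KernelSpec(
            self.kernel, self.sigma if self.kernel == "rbf" else None
        )

    def fit(self, X, y):
        X = _as2d(X)
        y = np.asarray(getattr(y, "values", y), dtype=float).ravel()
        if X.shape[0] != len(y):
            raise ValueError("X and y disagree on the number of samples")
        part = pair_partition(y, np.zeros_like(y))
        if part.n_pairs == 0:
            raise ValueError(
                "constant trait vector: no preference pairs to learn from"
            )
        n = len(y)
        K = compute_kernel(X, X, self._spec())
        lam = part.n_pairs * self.lam_tilde
        i, j = part.preference[:, 0], part.preference[:, 1]

        def fun(alpha):
            s = K @ alpha
            margins = np.maximum(0.0, 1.0 - s[i] + s[j])
            obj = 0.5 * lam * alpha @ s + (margins ** 2).sum()
            w = np.zeros(n)
            np.add.at(w, j, margins)
            np.subtract.at(w, i, margins)
            return obj, lam * s + 2.0 * (K @ w)

        res = optimize.minimize(
            fun,
            np.zeros(n),
            jac=True,
            method="L-BFGS-B",
            options={
                "maxiter": self.max_iter,
                "gtol": self.tol * n,
                "ftol": 0.0,
            },
        )
        self.X_ = X
        self.alpha_ = res.x
        self.lam_ = lam
        self.n_pairs_ = part.n_pairs
        self.objective_ = float(res.fun)
        self.n_iter_ = int(res.nit)
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        K_cross = compute_kernel(_as2d(X), self.X_, self._spec())
        return K_cross @ self.alpha_


def fit_ranksvm(X, y, lam_tilde: float, spec: KernelSpec | None = None,
                max_iter: int = 500) -> RankSVM:
    """Functional wrapper over :class:`RankSVM`."""
    spec = spec or KernelSpec()
    model = RankSVM(
        kernel=spec.kind,
        sigma=spec.sigma if spec.sigma is not None else 0.5,
        lam_tilde=lam_tilde,
        max_iter=max_iter,
    )
    return model.fit(X, y)
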