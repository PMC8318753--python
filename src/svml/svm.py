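"""Weighted soft-margin RBF-kernel SVM with an SMO-style dual solver.

The classifier solves the kernelized dual

    min_a  1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j) - sum_i a_i
    s.t.   sum_i y_i a_i = 0,   0 <= a_i <= C * v_i

where v_i in [0, 1] are per-sample curriculum weights (v_i = 0 excludes a
sample; v_i = 1 gives it the full box C).  The discriminant is the kernel
expansion over the Ns support vectors,

    f(x) = sum_{i=1..Ns} y_i beta_i K(x, x_i) + c,

with beta_i > 0 the Lagrange multipliers and c the classification
threshold.  The kernel is the radial basis K(x, x') = exp(-gamma ||x-x'||^2).

The solver is a two-variable working-set method (maximal-violating-pair
selection, as in SMO/LIBSVM) run until the KKT gap falls below ``tol``.
Starting from a = 0 the equality constraint sum_i y_i a_i = 0 is preserved
exactly by every update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import TrainingError, ValidationError

__all__ = [
    "KernelSpec",
    "SVMModel",
    "TrainReport",
    "rbf_kernel",
    "kernel_matrix",
    "train_weighted_svm",
    "decision_function",
    "predict",
    "correct_rate_weight",
    "hinge_losses",
]


@dataclass(frozen=True)
class KernelSpec:
    """Radial-basis kernel width gamma (> 0)."""

    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gamma) and self.gamma > 0):
            raise ValidationError(f"gamma must be positive and finite, got {self.gamma}")


def rbf_kernel(x: np.ndarray, x2: np.ndarray, spec: KernelSpec) -> float:
    """exp(-gamma ||x - x2||^2) for a single pair of vectors."""
    x = np.asarray(x, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x.shape != x2.shape:
        raise ValidationError(f"dimension mismatch: {x.shape} vs {x2.shape}")
    d2 = float(np.sum((x - x2) ** 2))
    return float(np.exp(-spec.gamma * d2))


def kernel_matrix(X: np.ndarray, Y: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """RBF Gram matrix between the rows of X (n x m) and Y (p x m)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValidationError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    d2 = (
        np.sum(X**2, axis=1)[:, None]
        + np.sum(Y**2, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-spec.gamma * d2)


@dataclass
class SVMModel:
    """Trained kernel expansion: support vectors, multipliers, threshold.

    ``dual_coef`` stores beta_i > 0; the signed expansion coefficient is
    ``support_labels * dual_coef``.  Optional z-score statistics
    (``feature_mean``/``feature_scale``) are applied to inputs at inference
    when present.
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    support_labels: np.ndarray
    bias: float
    kernel: KernelSpec
    C: float
    n_train: int
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    @property
    def n_support(self) -> int:
        return int(self.support_vectors.shape[0])

    def standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.feature_mean is not None:
            X = (X - self.feature_mean) / self.feature_scale
        return X


@dataclass
class TrainReport:
    """Solver diagnostics for one training run."""

    iterations: int
    dual_objective: float  # value of the minimized dual at termination
    kkt_violation: float  # maximal-violating-pair gap at termination
    w_t: float  # correct-rate discriminant weight, 1 - Ns/n
    converged: bool = True


def _smo(K: np.ndarray, y: np.ndarray, box: np.ndarray, tol: float, max_iter: int):
    """Maximal-violating-pair SMO on the dual; returns (alpha, iters, gap)."""
    n = y.size
    alpha = np.zeros(n)
    # gradient of the minimized dual: G_i = sum_j a_j y_i y_j K_ij - 1
    G = -np.ones(n)
    it = 0
    gap = np.inf
    while it < max_iter:
        nyG = -y * G
        up = ((y > 0) & (alpha < box - 1e-12)) | ((y < 0) & (alpha > 1e-12))
        low = ((y > 0) & (alpha > 1e-12)) | ((y < 0) & (alpha < box - 1e-12))
        if not up.any() or not low.any():
            gap = 0.0
            break
        i = int(np.argmax(np.where(up, nyG, -np.inf)))
        j = int(np.argmin(np.where(low, nyG, np.inf)))
        gap = nyG[i] - nyG[j]
        if gap <= tol:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        eta = max(eta, 1e-12)
        delta = gap / eta
        # alpha_i moves by +y_i*delta, alpha_j by -y_j*delta
        head_i = (box[i] - alpha[i]) if y[i] > 0 else alpha[i]
        head_j = alpha[j] if y[j] > 0 else (box[j] - alpha[j])
        delta = min(delta, head_i, head_j)
        alpha[i] += y[i] * delta
        alpha[j] -= y[j] * delta
        np.clip(alpha, 0.0, box, out=alpha)
        G += delta * y * (K[:, i] - K[:, j])
        it += 1
    return alpha, it, max(gap, 0.0)


def train_weighted_svm(
    X: np.ndarray,
    y: np.ndarray,
    v: np.ndarray | None = None,
    C: float = 10.0,
    kernel: KernelSpec = KernelSpec(),
    tol: float = 1e-3,
    max_iter: int | None = None,
    precomputed_kernel: np.ndarray | None = None,
) -> tuple[SVMModel, TrainReport]:
    """Train the weighted soft-margin SVM.

    Parameters
    ----------
    X, y
        Samples (n x m) and labels in {-1, +1}.
    v
        Per-sample weights in [0, 1]; the effective box is ``C * v_i`` and
        ``v_i = 0`` excludes the sample.  Default: all ones.
    C
        Soft-margin regularization parameter (> 0).
    tol
        KKT maximal-violating-pair gap at which the solver stops.
    precomputed_kernel
        Optional full Gram matrix of X (reused across curriculum rounds).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValidationError(f"X has {X.shape[0]} rows but y has {n} labels")
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValidationError("labels must be in {-1, +1}")
    if C <= 0:
        raise ValidationError(f"C must be > 0, got {C}")
    if v is None:
        v = np.ones(n)
    else:
        v = np.asarray(v, dtype=float).ravel()
        if v.size != n:
            raise ValidationError(f"v has {v.size} entries for {n} samples")
        if np.any((v < 0) | (v > 1)):
            raise ValidationError("weights v must lie in [0, 1]")
    active = v > 0
    if np.unique(y[active]).size < 2:
        raise TrainingError("training needs both classes with positive weight")

    K = precomputed_kernel if precomputed_kernel is not None else kernel_matrix(X, X, kernel)
    box = C * v
    if max_iter is None:
        max_iter = min(max(20_000, 10 * n * n), 500_000)
    alpha, iters, gap = _smo(K, y, box, tol, max_iter)
    if iters >= max_iter and gap > tol:
        warnings.warn(f"SMO hit the iteration cap with KKT gap {gap:.3g}", RuntimeWarning)

    Qa = (y * alpha) @ K  # s_i = f(x_i) without bias
    dual_obj = 0.5 * float(alpha @ (y * Qa)) - float(alpha.sum())

    # bias from free support vectors; fall back to the KKT-bound midpoint
    resid = y - Qa  # y_i - s_i
    free = (alpha > 1e-8 * C) & (alpha < box - 1e-8 * C)
    if free.any():
        bias = float(resid[free].mean())
    else:
        up = ((y > 0) & (alpha < box - 1e-12)) | ((y < 0) & (alpha > 1e-12))
        low = ((y > 0) & (alpha > 1e-12)) | ((y < 0) & (alpha < box - 1e-12))
        hi = resid[up].max() if up.any() else 0.0
        lo = resid[low].min() if low.any() else 0.0
        bias = float((hi + lo) / 2.0)

    sv = alpha > 1e-10
    model = SVMModel(
        support_vectors=X[sv].copy(),
        dual_coef=alpha[sv].copy(),
        support_labels=y[sv].copy(),
        bias=bias,
        kernel=kernel,
        C=C,
        n_train=n,
    )
    report = TrainReport(
        iterations=iters,
        dual_objective=dual_obj,
        kkt_violation=gap,
        w_t=correct_rate_weight(model.n_support, n),
        converged=gap <= tol,
    )
    return model, report


def decision_function(model: SVMModel, X: np.ndarray) -> np.ndarray | float:
    """Discriminant f(x) = sum_i y_i beta_i K(x, x_i) + c.

    Accepts a single vector or an (n x m) batch; returns a scalar or a
    1D array accordingly.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    Xs = model.standardize(X)
    if model.n_support == 0:
        f = np.full(Xs.shape[0], model.bias)
    else:
        if Xs.shape[1] != model.support_vectors.shape[1]:
            raise ValidationError(
                f"feature dimension {Xs.shape[1]} does not match model "
                f"dimension {model.support_vectors.shape[1]}"
            )
        Kx = kernel_matrix(Xs, model.support_vectors, model.kernel)
        f = Kx @ (model.support_labels * model.dual_coef) + model.bias
    return float(f[0]) if single else f


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray | int:
    """sign(f(x)) with the tie f(x) = 0 assigned to -1 (background)."""
    f = decision_function(model, X)
    if np.isscalar(f):
        return 1 if f > 0 else -1
    return np.where(np.asarray(f) > 0, 1, -1)


def correct_rate_weight(n_support: int, n: int) -> float:
    """Correct-rate discriminant weight w_t = 1 - Ns/n.

    Ns estimates the expected support-vector count E(SV) by the realized
    count of the trained model; n is the training-set size.  By the
    leave-one-out bound, Ns/n upper-bounds the expected test error of a
    separable machine, so w_t lower-bounds the expected correct rate.
    """
    if n <= 0:
        raise ValidationError(f"n must be positive, got {n}")
    if n_support < 0 or n_support > n:
        raise ValidationError(f"need 0 <= Ns <= n, got Ns={n_support}, n={n}")
    return 1.0 - n_support / n


def hinge_losses(model: SVMModel, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample hinge losses L_i = max(0, 1 - y_i f(x_i))."""
    y = np.asarray(y, dtype=float).ravel()
    f = np.atleast_1d(decision_function(model, X))
    if f.size != y.size:
        raise ValidationError(f"{f.size} decision values for {y.size} labels")
    return np.maximum(0.0, 1.0 - y * f)
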