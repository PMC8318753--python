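"""Self-paced curriculum training around the weighted SVM.

The curriculum minimizes, by alternating over the model and the sample
weights v in {0,1}^n,

    min_{model, v}  sum_i v_i L_i(model) + eta ||w||^2 - lambda sum_i v_i

where L_i is the hinge loss of sample i, ||w||^2 is the RKHS norm of the
decision function and the last term is the hard self-paced regularizer
f(v, lambda) = -lambda sum_i v_i.  For fixed model the v-step has the
closed form v_i = 1[L_i < lambda]: only samples easier than the current
pace lambda are kept.  lambda is annealed geometrically so that harder
samples are admitted round by round, until every sample is included.

The step-length parameter eta plays the role of the SVM trade-off; the two
are tied by eta = 1 / (2 * C), which makes each retraining step an exact
block-coordinate minimization of the objective above: the weighted-SVM
primal 1/2 ||w||^2 + C sum_i v_i L_i is the objective's model block scaled
by C.  One knob therefore controls both the inner solver and the reported
objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .svm import (
    KernelSpec,
    SVMModel,
    TrainReport,
    hinge_losses,
    kernel_matrix,
    train_weighted_svm,
)

__all__ = [
    "SelfPacedConfig",
    "SelfPacedState",
    "update_sample_weights",
    "objective_value",
    "self_paced_train",
]


@dataclass(frozen=True)
class SelfPacedConfig:
    """Hyperparameters of the curriculum.

    ``lambda0 = None`` sets the initial pace to the 60th percentile of the
    warm-up losses.  ``eta = None`` uses ``inner_C`` directly for the SVM;
    otherwise C = 1/(2*eta).
    """

    lambda0: float | None = None
    growth: float = 2.0
    eta: float | None = None
    max_rounds: int = 10
    inner_C: float = 10.0
    gamma: float = 0.5
    seed: int = 0
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.lambda0 is not None and self.lambda0 <= 0:
            raise ValidationError(f"lambda0 must be > 0, got {self.lambda0}")
        if self.growth <= 1:
            raise ValidationError(f"growth must be > 1, got {self.growth}")
        if self.max_rounds < 1:
            raise ValidationError(f"max_rounds must be >= 1, got {self.max_rounds}")
        if self.eta is not None and self.eta <= 0:
            raise ValidationError(f"eta must be > 0, got {self.eta}")
        if self.inner_C <= 0:
            raise ValidationError(f"inner_C must be > 0, got {self.inner_C}")


@dataclass
class SelfPacedState:
    """Trace of the curriculum: final weights, pace and objective history.

    ``objective_trace`` holds one entry per completed half-step as
    ``(round, phase, lambda, objective)`` with phase "train" or "v-update".
    """

    v: np.ndarray
    lambda_current: float
    rounds: int
    objective_trace: list = field(default_factory=list)
    n_included_trace: list = field(default_factory=list)
    warm_report: TrainReport | None = None
    final_report: TrainReport | None = None


def update_sample_weights(losses: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form v-step: v_i = 1 if L_i < lambda else 0.

    This is the minimizer of sum_i v_i L_i - lambda sum_i v_i over
    v in [0, 1]^n, which is attained at the vertices.
    """
    losses = np.asarray(losses, dtype=float).ravel()
    if np.any(losses < 0):
        raise ValidationError("losses must be non-negative")
    if lam <= 0:
        raise ValidationError(f"lambda must be > 0, got {lam}")
    return (losses < lam).astype(float)


def _rkhs_norm_sq(model: SVMModel) -> float:
    """||w||^2 = sum_ij a_i a_j y_i y_j K(x_i, x_j) over support vectors."""
    if model.n_support == 0:
        return 0.0
    coef = model.support_labels * model.dual_coef
    K = kernel_matrix(model.support_vectors, model.support_vectors, model.kernel)
    return float(coef @ K @ coef)


def objective_value(
    model: SVMModel,
    X: np.ndarray,
    y: np.ndarray,
    v: np.ndarray,
    lam: float,
    eta: float,
) -> float:
    """Curriculum objective sum_i v_i L_i + eta ||w||^2 - lambda sum_i v_i."""
    v = np.asarray(v, dtype=float).ravel()
    L = hinge_losses(model, X, y)
    if v.size != L.size:
        raise ValidationError(f"v has {v.size} entries for {L.size} samples")
    return float(v @ L + eta * _rkhs_norm_sq(model) - lam * v.sum())


def _round_C_eta(config: SelfPacedConfig) -> tuple[float, float]:
    if config.eta is not None:
        return 1.0 / (2.0 * config.eta), config.eta
    return config.inner_C, 1.0 / (2.0 * config.inner_C)


def self_paced_train(
    X: np.ndarray,
    y: np.ndarray,
    config: SelfPacedConfig = SelfPacedConfig(),
) -> tuple[SVMModel, SelfPacedState]:
    """Alternating minimization of the self-paced objective.

    Each round trains the weighted SVM at the current v, recomputes all
    hinge losses, thresholds them at lambda to refresh v, then grows
    lambda.  Training stops once every sample is included and v is stable,
    or after ``max_rounds``.  Initial losses come from an unweighted
    warm-up fit.  A round whose v would be all-zero or single-class falls
    back to v = 1 for that round (with a warning).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    kernel = KernelSpec(config.gamma)
    K = kernel_matrix(X, X, kernel)

    C_full, _ = _round_C_eta(config)
    model, warm_report = train_weighted_svm(
        X, y, None, C_full, kernel, tol=config.tol, precomputed_kernel=K
    )
    losses = hinge_losses(model, X, y)
    lam = config.lambda0
    if lam is None:
        lam = float(np.percentile(losses, 60.0))
        if lam <= 0:  # warm-up already separates everything
            lam = max(float(losses.max()), 1e-6) + 1e-6

    state = SelfPacedState(
        v=np.ones(n), lambda_current=lam, rounds=0, warm_report=warm_report
    )
    v = update_sample_weights(losses, lam)
    report = warm_report
    for rnd in range(1, config.max_rounds + 1):
        if v.sum() == 0 or np.unique(y[v > 0]).size < 2:
            warnings.warn(
                f"round {rnd}: curriculum kept an all-zero or single-class "
                "sample set; falling back to v = 1 for this round",
                RuntimeWarning,
            )
            v = np.ones(n)
        C, eta = _round_C_eta(config)
        model, report = train_weighted_svm(
            X, y, v, C, kernel, tol=config.tol, precomputed_kernel=K
        )
        state.objective_trace.append(
            (rnd, "train", lam, objective_value(model, X, y, v, lam, eta))
        )
        losses = hinge_losses(model, X, y)
        v_new = update_sample_weights(losses, lam)
        state.objective_trace.append(
            (rnd, "v-update", lam, objective_value(model, X, y, v_new, lam, eta))
        )
        state.n_included_trace.append(int(v_new.sum()))
        state.rounds = rnd
        if v_new.sum() == n and np.array_equal(v_new, v):
            v = v_new
            break
        v = v_new
        lam *= config.growth

    state.v = v
    state.lambda_current = lam
    state.final_report = report
    return model, state
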