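import numpy as np
import pytest
from scipy.optimize import minimize

from svml.exceptions import TrainingError, ValidationError
from svml.svm import (
    KernelSpec,
    SVMModel,
    correct_rate_weight,
    decision_function,
    hinge_losses,
    kernel_matrix,
    predict,
    rbf_kernel,
    train_weighted_svm,
)


def qp_dual_objective(X, y, C_box, gamma):
    """Independent dual solution via SLSQP (not the SMO path)."""
    K = np.exp(-gamma * ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    Q = np.outer(y, y) * K
    n = len(y)
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(n),
        jac=lambda a: Q @ a - 1.0,
        method="SLSQP",
        bounds=[(0.0, c) for c in np.broadcast_to(C_box, (n,))],
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        options={"maxiter": 2000, "ftol": 1e-12},
    )
    assert res.success
    return res.fun


def random_toy(seed, n_max=30):
    r = np.random.default_rng(seed)
    n = int(r.integers(6, n_max + 1))
    X = r.normal(size=(n, 2))
    y = np.where(r.random(n) < 0.5, 1.0, -1.0)
    if abs(y.sum()) == n:
        y[0] *= -1
    return X, y


class TestRbfKernel:
    def test_zero_distance_is_one(self, rng):
        x = rng.normal(size=5)
        assert rbf_kernel(x, x, KernelSpec(3.0)) == 1.0

    def test_unit_distance_log2_gamma_is_half(self):
        assert rbf_kernel([0.0], [1.0], KernelSpec(np.log(2.0))) == pytest.approx(0.5)

    def test_matches_componentwise_formula(self, rng):
        x, x2 = rng.normal(size=7), rng.normal(size=7)
        g = 0.7
        expected = np.exp(-g * sum((a - b) ** 2 for a, b in zip(x, x2)))
        assert rbf_kernel(x, x2, KernelSpec(g)) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(20):
            x, x2 = rng.normal(size=3), rng.normal(size=3)
            k = rbf_kernel(x, x2, KernelSpec(1.3))
            assert k == rbf_kernel(x2, x, KernelSpec(1.3))
            assert 0 < k <= 1

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            rbf_kernel([1.0, 2.0], [1.0], KernelSpec(1.0))


class TestTraining:
    def test_wide_margin_toy_perfectly_classified(self):
        X = np.array([[-2.0, 0.0], [-2.5, 0.5], [2.0, 0.0], [2.5, -0.5]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        model, report = train_weighted_svm(X, y, C=5.0, kernel=KernelSpec(0.5))
        assert np.all(predict(model, X) == y)
        oracle = qp_dual_objective(X, y, 5.0, 0.5)
        assert report.dual_objective == pytest.approx(oracle, abs=1e-4)

    @pytest.mark.parametrize("seed", range(8))
    def test_dual_objective_matches_qp_oracle(self, seed):
        X, y = random_toy(seed)
        C, gamma = 5.0, 1.0
        model, report = train_weighted_svm(X, y, C=C, kernel=KernelSpec(gamma))
        oracle = qp_dual_objective(X, y, C, gamma)
        assert report.dual_objective == pytest.approx(oracle, abs=1e-4)
        assert report.kkt_violation <= 1e-3
        # dual feasibility
        signed = model.dual_coef * model.support_labels
        assert abs(signed.sum()) <= 1e-6 * max(model.dual_coef.sum(), 1.0)
        assert np.all(model.dual_coef > 0)
        assert np.all(model.dual_coef <= C + 1e-9)

    def test_all_ones_weights_identical_to_unweighted(self):
        X, y = random_toy(42)
        m1, _ = train_weighted_svm(X, y, v=np.ones(len(y)), C=3.0, kernel=KernelSpec(0.8))
        m2, _ = train_weighted_svm(X, y, v=None, C=3.0, kernel=KernelSpec(0.8))
        assert np.array_equal(m1.support_vectors, m2.support_vectors)
        assert np.allclose(m1.dual_coef, m2.dual_coef, atol=1e-6)

    def test_zero_weight_equals_dropping_the_sample(self):
        X, y = random_toy(7)
        v = np.ones(len(y))
        v[3] = 0.0
        m1, _ = train_weighted_svm(X, y, v=v, C=2.0, kernel=KernelSpec(1.0))
        keep = np.arange(len(y)) != 3
        m2, _ = train_weighted_svm(X[keep], y[keep], C=2.0, kernel=KernelSpec(1.0))
        grid = np.random.default_rng(0).normal(size=(20, 2))
        assert np.allclose(decision_function(m1, grid), decision_function(m2, grid), atol=1e-3)

    def test_single_effective_class_raises(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        y = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        v = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
        with pytest.raises(TrainingError):
            train_weighted_svm(X, y, v=v)

    def test_non_finite_features_rejected(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValidationError):
            train_weighted_svm(X, np.array([1.0, -1.0]))

    def test_hinge_loss_sum_non_increasing_in_C(self):
        X, y = random_toy(3)
        sums = []
        for C in (0.1, 1.0, 10.0, 100.0):
            model, _ = train_weighted_svm(X, y, C=C, kernel=KernelSpec(1.0))
            sums.append(hinge_losses(model, X, y).sum())
        assert all(a >= b - 1e-6 for a, b in zip(sums, sums[1:]))


class TestDiscriminant:
    def test_empty_support_set_returns_bias(self):
        model = SVMModel(
            support_vectors=np.empty((0, 2)),
            dual_coef=np.empty(0),
            support_labels=np.empty(0),
            bias=0.37,
            kernel=KernelSpec(1.0),
            C=1.0,
            n_train=4,
        )
        assert decision_function(model, np.array([1.0, 2.0])) == 0.37
        assert predict(model, np.array([1.0, 2.0])) == 1

    def test_matches_independent_resummation(self, rng):
        X, y = random_toy(9)
        model, _ = train_weighted_svm(X, y, C=4.0, kernel=KernelSpec(0.6))
        x = rng.normal(size=2)
        expected = model.bias + sum(
            yi * bi * rbf_kernel(x, sv, model.kernel)
            for yi, bi, sv in zip(model.support_labels, model.dual_coef, model.support_vectors)
        )
        assert decision_function(model, x) == pytest.approx(expected, rel=1e-10)

    def test_free_support_vectors_sit_on_the_margin(self):
        X = np.array([[-2.0, 0.0], [-2.5, 0.5], [2.0, 0.0], [2.5, -0.5]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        model, _ = train_weighted_svm(X, y, C=10.0, kernel=KernelSpec(0.5))
        f = decision_function(model, model.support_vectors)
        free = model.dual_coef < 10.0 - 1e-6
        assert np.all(model.support_labels[free] * f[free] >= 1 - 1e-5)

    def test_tie_break_is_background(self):
        model = SVMModel(
            support_vectors=np.empty((0, 1)),
            dual_coef=np.empty(0),
            support_labels=np.empty(0),
            bias=0.0,
            kernel=KernelSpec(1.0),
            C=1.0,
            n_train=2,
        )
        assert predict(model, np.array([0.0])) == -1

    def test_dimension_mismatch(self):
        X, y = random_toy(2)
        model, _ = train_weighted_svm(X, y)
        with pytest.raises(ValidationError):
            decision_function(model, np.ones((3, 5)))


class TestCorrectRateWeight:
    @pytest.mark.parametrize("ns, n, expected", [(3, 10, 0.7), (0, 5, 1.0), (7, 7, 0.0)])
    def test_arithmetic(self, ns, n, expected):
        assert correct_rate_weight(ns, n) == pytest.approx(expected)

    def test_invalid_counts(self):
        with pytest.raises(ValidationError):
            correct_rate_weight(1, 0)
        with pytest.raises(ValidationError):
            correct_rate_weight(5, 3)

    def test_reported_by_training(self):
        X, y = random_toy(4)
        model, report = train_weighted_svm(X, y)
        assert report.w_t == pytest.approx(1.0 - model.n_support / len(y))
        assert 0.0 <= report.w_t <= 1.0


class TestHingeLosses:
    def test_matches_elementwise_recomputation(self, rng):
        X, y = random_toy(11)
        model, _ = train_weighted_svm(X, y, C=2.0)
        L = hinge_losses(model, X, y)
        f = decision_function(model, X)
        expected = [max(0.0, 1.0 - yi * fi) for yi, fi in zip(y, f)]
        assert np.allclose(L, expected)
        assert np.all(L >= 0)

    def test_zero_decision_value_gives_unit_loss(self):
        model = SVMModel(
            support_vectors=np.empty((0, 1)),
            dual_coef=np.empty(0),
            support_labels=np.empty(0),
            bias=0.0,
            kernel=KernelSpec(1.0),
            C=1.0,
            n_train=2,
        )
        assert hinge_losses(model, np.array([[1.0], [2.0]]), np.array([1.0, -1.0])).tolist() == [1.0, 1.0]


def test_kernel_matrix_agrees_with_pairwise_kernel(rng):
    X = rng.normal(size=(6, 3))
    Y = rng.normal(size=(4, 3))
    K = kernel_matrix(X, Y, KernelSpec(0.9))
    for i in range(6):
        for j in range(4):
            assert K[i, j] == pytest.approx(rbf_kernel(X[i], Y[j], KernelSpec(0.9)), rel=1e-12)
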