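"""The pairwise-model objective: densities, gradients, analytic identities."""

import numpy as np
import pytest
from scipy.integrate import quad

from glassyhrv.model import (
    CouplingModel,
    conditional_log_density,
    kernel_determinant_check,
    lambda2_from_second_moment,
    objective_gradient,
    pseudo_log_likelihood,
    regularized_objective,
    temporal_penalty,
)
from tests.conftest import make_standardized


def recursive_series(J, h, n, start):
    """Series satisfying z_t = h + sum J(tau) z_{t-tau} exactly (zero residuals)."""
    z = list(start)
    T = len(J)
    for _ in range(n - len(start)):
        z.append(h + sum(J[t] * z[-1 - t] for t in range(T)))
    return np.asarray(z)


class TestConditionalLogDensity:
    def test_standard_normal_at_zero(self):
        model = CouplingModel(T=2, J=[0.0, 0.0], h=0.0)
        assert conditional_log_density(0.0, [0.3, -0.7], model) == pytest.approx(
            -0.9189385, abs=1e-6
        )

    def test_zero_residual_case(self):
        model = CouplingModel(T=1, J=[0.5], h=0.2)
        assert conditional_log_density(0.7, [1.0], model) == pytest.approx(-0.9189385, abs=1e-6)

    def test_window_ordering_oldest_to_newest(self):
        # J(1) couples to the NEWEST window entry (distance 1 into the past)
        model = CouplingModel(T=2, J=[1.0, 0.0], h=0.0)
        assert conditional_log_density(2.0, [5.0, 2.0], model) == pytest.approx(
            -0.9189385, abs=1e-6
        )

    def test_density_normalizes_by_quadrature(self, rng):
        model = CouplingModel(T=4, J=rng.normal(size=4) * 0.3, h=0.1)
        window = rng.normal(size=4)
        total, _ = quad(
            lambda z: np.exp(conditional_log_density(z, window, model)), -10, 10
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_wrong_window_length(self):
        model = CouplingModel(T=3, J=[0.1, 0.1, 0.1], h=0.0)
        with pytest.raises(ValueError):
            conditional_log_density(0.0, [1.0, 2.0], model)


class TestPseudoLogLikelihood:
    def test_zero_residual_series_attains_maximum(self):
        J, h = [0.4, -0.2], 0.1
        z = recursive_series(J, h, 30, [0.5, -0.3])
        model = CouplingModel(T=2, J=J, h=h)
        pll = pseudo_log_likelihood(make_standardized_raw(z), model)
        assert pll == pytest.approx(0.0, abs=1e-20)

    def test_single_window_case(self, rng):
        z = rng.normal(size=4)
        model = CouplingModel(T=3, J=[0.2, -0.1, 0.05], h=0.3)
        resid = z[3] - 0.3 - (0.2 * z[2] - 0.1 * z[1] + 0.05 * z[0])
        expected = -0.5 * resid**2
        assert pseudo_log_likelihood(z, model) == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_loop(self, rng):
        z = rng.normal(size=50)
        model = CouplingModel(T=3, J=[0.3, -0.2, 0.1], h=0.05)
        n, T = 50, 3
        total = 0.0
        for L in range(T, n):  # window positions, 0-based target index L
            pred = model.h + sum(model.J[t] * z[L - 1 - t] for t in range(T))
            total += (z[L] - pred) ** 2
        expected = -total / (2 * (n - T))
        assert pseudo_log_likelihood(z, model) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive(self, rng):
        z = rng.normal(size=100)
        model = CouplingModel(T=5, J=rng.normal(size=5) * 0.2, h=0.0)
        assert pseudo_log_likelihood(z, model) <= 0.0

    def test_series_shorter_than_cutoff_rejected(self, rng):
        model = CouplingModel(T=10, J=np.zeros(10), h=0.0)
        with pytest.raises(ValueError):
            pseudo_log_likelihood(rng.normal(size=10), model)


def make_standardized_raw(z):
    """Wrap raw values without re-standardizing them."""
    from glassyhrv.preprocess import StandardizedSeries

    return StandardizedSeries(values=np.asarray(z, dtype=float), patient_id="raw")


class TestRegularizedObjective:
    def test_zero_parameters_no_penalty(self, rng):
        z = rng.normal(size=60)
        model = CouplingModel(T=2, J=[0.0, 0.0], h=0.0)
        assert regularized_objective(z, model, 5.0) == pytest.approx(
            pseudo_log_likelihood(z, model), abs=1e-15
        )

    def test_hand_evaluated_penalty(self):
        # lambda=2, J=(1,1), h=0, zero residuals: -(log^2 2 + log^2 3)
        J, h = [1.0, 1.0], 0.0
        z = recursive_series(J, h, 20, [0.01, 0.02])
        model = CouplingModel(T=2, J=J, h=h)
        assert regularized_objective(z, model, 2.0) == pytest.approx(-1.687402, abs=1e-5)

    def test_monotone_in_lambda(self, rng):
        z = rng.normal(size=80)
        model = CouplingModel(T=3, J=[0.2, 0.1, -0.1], h=0.05)
        vals = [regularized_objective(z, model, lam) for lam in [0.0, 0.1, 1.0, 10.0]]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_negative_lambda_rejected(self, rng):
        model = CouplingModel(T=1, J=[0.1], h=0.0)
        with pytest.raises(ValueError):
            regularized_objective(rng.normal(size=10), model, -1.0)


class TestObjectiveGradient:
    def test_zero_residual_stationary_point(self):
        J, h = [0.3, -0.1], 0.05
        z = recursive_series(J, h, 40, [0.4, -0.2])
        grad = objective_gradient(z, CouplingModel(T=2, J=J, h=h), 0.0)
        assert np.max(np.abs(grad.grad_J)) < 1e-10
        assert abs(grad.grad_h) < 1e-10

    def test_hand_computed_toy_case(self):
        # 4-point series, T=1: two windows, residuals and gradient by hand
        z = np.array([1.0, 2.0, -1.0, 0.5])
        J, h, lam = [0.5], 0.1, 0.2
        model = CouplingModel(T=1, J=J, h=h)
        # Delta_L = (z[L] - h - J z[L-1]) / (N - T), L = 1..3
        d = (z[1:] - h - 0.5 * z[:-1]) / 3.0
        grad = objective_gradient(z, model, lam)
        assert grad.residuals == pytest.approx(d, abs=1e-15)
        f1 = np.log(2.0) ** 2
        assert grad.grad_J[0] == pytest.approx(float(d @ z[:-1]) - lam * f1 * 0.5, abs=1e-14)
        assert grad.grad_h == pytest.approx(float(d.sum()) - lam * 0.1, abs=1e-14)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_finite_differences(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(50, 300))
        T = int(rng.integers(1, 21))
        z = rng.normal(size=n)
        J = rng.normal(size=T) * 0.2
        h = float(rng.normal() * 0.1)
        lam = float(rng.uniform(0, 0.5))
        grad = objective_gradient(z, CouplingModel(T=T, J=J, h=h), lam)
        eps = 1e-6

        def obj(Jv, hv):
            return regularized_objective(z, CouplingModel(T=T, J=Jv, h=hv), lam)

        for idx in rng.choice(T, size=min(3, T), replace=False):
            Jp, Jm = J.copy(), J.copy()
            Jp[idx] += eps
            Jm[idx] -= eps
            fd = (obj(Jp, h) - obj(Jm, h)) / (2 * eps)
            assert grad.grad_J[idx] == pytest.approx(fd, rel=1e-6, abs=1e-9)
        fd_h = (obj(J, h + eps) - obj(J, h - eps)) / (2 * eps)
        assert grad.grad_h == pytest.approx(fd_h, rel=1e-6, abs=1e-9)

    def test_shift_equivariance_of_residuals(self, rng):
        # adding c to the series shifts residuals exactly as h -> h + c(1 - sum J)
        z = rng.normal(size=100)
        J = rng.normal(size=4) * 0.2
        c = 0.7
        h = 0.1
        shifted_h = h + c * (1.0 - J.sum())
        g1 = objective_gradient(z, CouplingModel(T=4, J=J, h=h), 0.0)
        g2 = objective_gradient(z + c, CouplingModel(T=4, J=J, h=shifted_h), 0.0)
        assert g2.residuals == pytest.approx(g1.residuals, abs=1e-12)


class TestAnalyticIdentities:
    def test_lambda2_standardized(self):
        assert lambda2_from_second_moment(1.0) == -0.5

    def test_lambda2_inversion(self):
        assert lambda2_from_second_moment(0.5) == pytest.approx(-1.0)

    def test_lambda2_requires_positive_moment(self):
        with pytest.raises(ValueError):
            lambda2_from_second_moment(0.0)

    def test_lambda2_monte_carlo(self):
        # prior-only model: z ~ N(0, mu2) reproduces the second moment
        mu2 = 0.8
        lam2 = lambda2_from_second_moment(mu2)
        rng = np.random.default_rng(7)
        draws = rng.normal(scale=np.sqrt(-1.0 / (2 * lam2)), size=1_000_000)
        se = np.sqrt(2.0) * mu2 / 1000.0  # std error of the second moment
        assert np.mean(draws**2) == pytest.approx(mu2, abs=3 * se)

    @pytest.mark.parametrize("n", [1, 5, 8])
    def test_kernel_determinant(self, n, rng):
        lam_tau = rng.normal(size=max(n - 1, 1))
        numeric, analytic = kernel_determinant_check(-0.5, lam_tau, n)
        assert analytic == pytest.approx((-0.5) ** n)
        assert numeric == pytest.approx(analytic, rel=1e-10)

    def test_temporal_penalty_values(self):
        f = temporal_penalty(3)
        assert f == pytest.approx(np.log(np.array([2.0, 3.0, 4.0])) ** 2)
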