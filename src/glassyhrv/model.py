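"""The maximum-entropy pairwise model and its pseudo-likelihood objective.

Constraining the mean, second moment and two-point correlations of a
standardized series yields an exponential family with a standard-normal
prior per beat, a bias h and distance-dependent couplings J(tau).  The
conditional density of the next beat given a length-T past window is then
Gaussian with unit variance around the convolution mean

    m = h + sum_{tau=1..T} J(tau) * z_{t - tau},

which makes the pseudo-likelihood a (negative) mean squared residual.  The
regularizer penalizes h quadratically and J(tau) with the mild temporal
weight f(tau) = log^2(1 + tau).

Window-ordering contract: every ``window`` argument is ordered oldest ->
newest, i.e. ``window[-tau]`` is the sample at distance ``tau`` in the past.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CouplingModel",
    "GradientState",
    "temporal_penalty",
    "design_matrix",
    "conditional_log_density",
    "pseudo_log_likelihood",
    "regularized_objective",
    "objective_gradient",
    "lambda2_from_second_moment",
    "kernel_determinant_check",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class CouplingModel:
    """Inferred pairwise model: couplings J(tau), tau = 1..T, and bias h.

    ``sigma_J`` / ``sigma_h`` are across-minibatch standard deviations filled
    in by :func:`glassyhrv.inference.resampled_inference`; point estimates
    from a single fit carry zeros there.
    """

    T: int
    J: np.ndarray
    h: float
    sigma_J: np.ndarray | None = None
    sigma_h: float = 0.0
    class_label: str = "UNKNOWN"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.sigma_J is None:
            self.sigma_J = np.zeros(self.T)
        self.sigma_J = np.asarray(self.sigma_J, dtype=float)
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.J.shape != (self.T,) or self.sigma_J.shape != (self.T,):
            raise ValueError("J and sigma_J must both have length T")
        if np.any(self.sigma_J < 0):
            raise ValueError("sigma_J must be nonnegative")


@dataclass(frozen=True)
class GradientState:
    """Ascent gradient of the regularized objective plus the residual field."""

    residuals: np.ndarray  # Delta_L over window positions, length N - T
    grad_J: np.ndarray
    grad_h: float


def temporal_penalty(T: int) -> np.ndarray:
    """Regularization weights f(tau) = log^2(1 + tau) for tau = 1..T."""
    tau = np.arange(1, T + 1, dtype=float)
    return np.log1p(tau) ** 2


def design_matrix(z: np.ndarray, T: int) -> np.ndarray:
    """Lagged design matrix X with X[i, tau-1] = z[T + i - tau].

    Row i holds the length-T past of sample z[T + i], ordered by increasing
    lag tau (most recent past first).  Shape (N - T, T); a stride view, so
    callers must not mutate it.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    if n <= T:
        raise ValueError(f"series length N={n} must exceed the cutoff T={T}")
    return sliding_window_view(z, T)[: n - T, ::-1]


def _series_values(z) -> np.ndarray:
    return z.values if hasattr(z, "values") else np.asarray(z, dtype=float)


def conditional_log_density(z_next: float, window, model: CouplingModel) -> float:
    """Log density of the next beat given a length-T past window.

    Returns -0.5*log(2*pi) - 0.5*(z_next - m)^2 with the convolution mean m;
    the Gaussian constant is retained so the density integrates to one.
    """
    w = np.asarray(window, dtype=float)
    if w.shape != (model.T,):
        raise ValueError(f"window must have length T={model.T}, got {w.shape}")
    mean = model.h + float(model.J @ w[::-1])
    return -0.5 * LOG_2PI - 0.5 * (float(z_next) - mean) ** 2


def _residuals(z: np.ndarray, model: CouplingModel) -> np.ndarray:
    """Raw residuals z_{L+1} - h - sum_tau J(tau) z_{L+1-tau}, length N-T."""
    X = design_matrix(z, model.T)
    return z[model.T :] - model.h - X @ model.J


def pseudo_log_likelihood(z, model: CouplingModel) -> float:
    """Sliding-window pseudo-log-likelihood, a nonpositive quantity.

    Equals -(1/(2(N-T))) * sum of squared one-step-prediction residuals;
    the Gaussian constant is discarded, so the maximum attainable value is 0
    (reached only by an exactly self-consistent series).
    """
    zv = _series_values(z)
    r = _residuals(zv, model)
    return -0.5 * float(r @ r) / r.size


def regularized_objective(z, model: CouplingModel, lam: float) -> float:
    """Pseudo-log-likelihood minus the quadratic penalties on h and J."""
    if lam < 0:
        raise ValueError("regularization weight must be nonnegative")
    pen = 0.5 * lam * (model.h**2 + float(temporal_penalty(model.T) @ model.J**2))
    return pseudo_log_likelihood(z, model) - pen


def objective_gradient(z, model: CouplingModel, lam: float) -> GradientState:
    """Ascent gradient of :func:`regularized_objective` w.r.t. (J, h).

    Delta_L = residual / (N - T); grad J(tau) = sum_L Delta_L z_{L+1-tau}
    - lam f(tau) J(tau); grad h = sum_L Delta_L - lam h.
    """
    if lam < 0:
        raise ValueError("regularization weight must be nonnegative")
    zv = _series_values(z)
    X = design_matrix(zv, model.T)
    delta = (zv[model.T :] - model.h - X @ model.J) / X.shape[0]
    grad_J = X.T @ delta - lam * temporal_penalty(model.T) * model.J
    grad_h = float(delta.sum()) - lam * model.h
    return GradientState(residuals=delta, grad_J=grad_J, grad_h=grad_h)


def lambda2_from_second_moment(mu2: float) -> float:
    """Lagrange multiplier on the second moment when couplings and bias vanish.

    The moment condition mu2 = -1/(2*lambda2) inverts to lambda2 = -1/(2*mu2);
    a standardized series (mu2 = 1) gives exactly -1/2.
    """
    if mu2 <= 0:
        raise ValueError("second moment must be positive")
    return -1.0 / (2.0 * mu2)


def kernel_determinant_check(lambda2: float, lam_tau, N: int) -> tuple[float, float]:
    """Determinant of the interaction kernel lambda2*I + Lambda vs lambda2**N.

    Lambda is the strictly upper-triangular Toeplitz matrix with
    Lambda[n, m] = lam_tau[m - n - 1] for m > n, so the kernel is triangular
    and its determinant is the product of the diagonal, lambda2**N.  Both the
    numeric determinant and the analytic value are returned for comparison.
    """
    if not 1 <= N <= 12:
        raise ValueError("explicit construction supported for 1 <= N <= 12")
    lam_tau = np.asarray(lam_tau, dtype=float)
    K = lambda2 * np.eye(N)
    for offset in range(1, N):
        if offset - 1 < lam_tau.size:
            K += np.diag(np.full(N - offset, lam_tau[offset - 1]), k=offset)
    numeric = float(np.linalg.det(K))
    analytic = float(lambda2**N)
    return numeric, analytic
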