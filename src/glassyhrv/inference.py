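"""AdaGrad ascent of the regularized pseudo-likelihood with minibatch
resampling for uncertainty estimation.

The objective is quadratic in (J, h), so each series is reduced once to its
sufficient statistics (lagged Gram matrix, cross moments); every ascent
epoch then costs O(T^2) regardless of series length, and the gradient is
algebraically identical to :func:`glassyhrv.model.objective_gradient`
averaged over the batch.

Uncertainties follow the resampling scheme of the study design: the same
fit is repeated on M random patient subsets of size n, and the across-batch
mean and standard deviation of each parameter are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glassyhrv.model import CouplingModel, design_matrix, temporal_penalty

__all__ = [
    "OptimizerState",
    "ResamplingPlan",
    "SeriesStats",
    "series_stats",
    "adagrad_step",
    "fit_batch",
    "resampled_inference",
]


@dataclass
class OptimizerState:
    """Per-parameter AdaGrad accumulators (squared-gradient sums)."""

    acc_J: np.ndarray
    acc_h: float = 0.0
    learning_rate: float = 0.05
    epsilon: float = 1e-8
    epoch: int = 0
    last_objective: float = -np.inf

    @classmethod
    def init(cls, T: int, learning_rate: float = 0.05, epsilon: float = 1e-8) -> "OptimizerState":
        return cls(acc_J=np.zeros(T), learning_rate=learning_rate, epsilon=epsilon)


@dataclass(frozen=True)
class ResamplingPlan:
    """M minibatches of n distinct series each, reproducible from the seed.

    Batches are subsets of patient series, drawn without replacement within
    a batch and independently across batches.
    """

    n_batches: int
    batch_size: int
    seed: int

    def memberships(self, pool_size: int) -> list[np.ndarray]:
        if pool_size < self.batch_size:
            raise ValueError(
                f"pool of {pool_size} series is smaller than batch_size={self.batch_size}"
            )
        rng = np.random.default_rng(self.seed)
        return [
            rng.choice(pool_size, size=self.batch_size, replace=False)
            for _ in range(self.n_batches)
        ]


@dataclass(frozen=True)
class SeriesStats:
    """Sufficient statistics of one series for the quadratic objective.

    With X the lagged design matrix and y = z[T:] (m = N - T rows):
    G = X'X, c = X'y, s = X'1, y_sum = 1'y, y_sq = y'y.
    """

    m: int
    G: np.ndarray
    c: np.ndarray
    s: np.ndarray
    y_sum: float
    y_sq: float


def series_stats(z, T: int) -> SeriesStats:
    """Reduce one standardized series to its quadratic-objective statistics."""
    zv = z.values if hasattr(z, "values") else np.asarray(z, dtype=float)
    X = np.ascontiguousarray(design_matrix(zv, T))
    y = zv[T:]
    return SeriesStats(
        m=y.size,
        G=X.T @ X,
        c=X.T @ y,
        s=X.sum(axis=0),
        y_sum=float(y.sum()),
        y_sq=float(y @ y),
    )


def _batch_objective(stats, J, h, lam, f) -> float:
    vals = np.empty(len(stats))
    for k, st in enumerate(stats):
        quad = (
            st.y_sq
            - 2.0 * h * st.y_sum
            - 2.0 * float(st.c @ J)
            + 2.0 * h * float(st.s @ J)
            + float(J @ (st.G @ J))
            + st.m * h * h
        )
        vals[k] = -0.5 * quad / st.m
    pen = 0.5 * lam * (h * h + float(f @ (J * J)))
    return float(vals.mean()) - pen


def _batch_gradient(stats, J, h, lam, f):
    gJ = np.zeros_like(J)
    gh = 0.0
    for st in stats:
        gJ += (st.c - h * st.s - st.G @ J) / st.m
        gh += (st.y_sum - float(st.s @ J) - st.m * h) / st.m
    gJ /= len(stats)
    gh /= len(stats)
    return gJ - lam * f * J, gh - lam * h


def adagrad_step(state: OptimizerState, grad_J: np.ndarray, grad_h: float, J: np.ndarray, h: float):
    """One AdaGrad ascent step: p += lr * g / (sqrt(acc) + eps), acc += g^2."""
    if not (np.all(np.isfinite(grad_J)) and np.isfinite(grad_h)):
        bad = "h" if not np.isfinite(grad_h) else f"J({int(np.argmax(~np.isfinite(grad_J))) + 1})"
        raise FloatingPointError(f"non-finite gradient for parameter {bad}")
    state.acc_J = state.acc_J + grad_J**2
    state.acc_h = state.acc_h + grad_h**2
    J = J + state.learning_rate * grad_J / (np.sqrt(state.acc_J) + state.epsilon)
    h = h + state.learning_rate * grad_h / (np.sqrt(state.acc_h) + state.epsilon)
    state.epoch += 1
    return J, h, state


def fit_batch(batch, config, stats=None) -> CouplingModel:
    """Maximize the batch-averaged regularized objective by AdaGrad ascent.

    Parameters start at J = 0, h = 0 (the regularizer's minimum) and ascend
    until the gradient infinity-norm drops below ``config.tolerance`` or
    ``config.max_epochs`` is reached; in the latter case the best-so-far
    parameters are returned with ``meta['converged'] = False``.

    ``stats`` may carry precomputed :class:`SeriesStats` to avoid re-reducing
    the same series across minibatches.
    """
    T, lam = config.T, config.reg_weight
    if stats is None:
        stats = [series_stats(z, T) for z in batch]
    if not stats:
        raise ValueError("fit_batch requires a nonempty batch")
    f = temporal_penalty(T)
    J = np.zeros(T)
    h = 0.0
    state = OptimizerState.init(T, config.learning_rate, config.epsilon)
    best = (-np.inf, J, h)
    history = []
    grad_norm = np.inf
    for _ in range(config.max_epochs):
        gJ, gh = _batch_gradient(stats, J, h, lam, f)
        grad_norm = max(float(np.max(np.abs(gJ))), abs(gh))
        if grad_norm < config.tolerance:
            break
        J, h, state = adagrad_step(state, gJ, gh, J, h)
        obj = _batch_objective(stats, J, h, lam, f)
        state.last_objective = obj
        history.append(obj)
        if obj > best[0]:
            best = (obj, J.copy(), h)
    converged = grad_norm < config.tolerance
    if not converged and best[0] > -np.inf:
        _, J, h = best
    return CouplingModel(
        T=T,
        J=J,
        h=float(h),
        class_label=getattr(batch[0], "class_label", "UNKNOWN") if batch else "UNKNOWN",
        meta={
            "converged": converged,
            "epochs": state.epoch,
            "grad_inf_norm": grad_norm,
            "objective": history[-1] if history else _batch_objective(stats, J, h, lam, f),
            "objective_history": history,
        },
    )


def resampled_inference(class_series, plan: ResamplingPlan, config) -> CouplingModel:
    """Minibatch-resampled inference: across-batch mean and std of (J, h).

    Runs :func:`fit_batch` on ``plan.n_batches`` random subsets of
    ``plan.batch_size`` series; J and h are across-batch means, sigma_J and
    sigma_h the across-batch standard deviations.  Fully reproducible from
    ``plan.seed``.
    """
    series = list(class_series)
    members = plan.memberships(len(series))
    # reduce each distinct series once; minibatches then reuse the statistics
    needed = sorted({int(i) for idx in members for i in idx})
    cache = {i: series_stats(series[i], config.T) for i in needed}
    Js, hs, n_unconverged = [], [], 0
    for idx in members:
        fit = fit_batch(
            [series[i] for i in idx], config, stats=[cache[int(i)] for i in idx]
        )
        Js.append(fit.J)
        hs.append(fit.h)
        n_unconverged += not fit.meta["converged"]
    Js = np.asarray(Js)
    hs = np.asarray(hs)
    labels = {getattr(s, "class_label", "UNKNOWN") for s in series}
    return CouplingModel(
        T=config.T,
        J=Js.mean(axis=0),
        h=float(hs.mean()),
        sigma_J=Js.std(axis=0),
        sigma_h=float(hs.std()),
        class_label=labels.pop() if len(labels) == 1 else "MIXED",
        meta={
            "n_batches": plan.n_batches,
            "batch_size": plan.batch_size,
            "seed": plan.seed,
            "n_unconverged": n_unconverged,
        },
    )
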