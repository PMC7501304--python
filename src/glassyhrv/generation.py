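"""Synthetic-series generation by convolution with noisy couplings.

An inferred model generates a synthetic series by sliding its length-T
coupling window along an *experimental* seed series and emitting, at each
position, the conditional mode h + sum_tau J(tau) z (no innovation noise).
Stochasticity enters only through the couplings: each generated series uses
one noisy draw Jbar(tau) = J(tau) + eta * sigma_J(tau), eta ~ N(0, 1).
The raw output of the convolution is no longer standardized; that is redone
explicitly afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from glassyhrv.model import CouplingModel, design_matrix
from glassyhrv.preprocess import StandardizedSeries, standardize_values

__all__ = ["NoisyCouplings", "perturb_couplings", "convolve_generate", "finalize_synthetic"]


@dataclass(frozen=True)
class NoisyCouplings:
    """One noisy realization of the inferred couplings, tied to its seed."""

    J_bar: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "J_bar", np.asarray(self.J_bar, dtype=float))


def perturb_couplings(model: CouplingModel, seed: int) -> NoisyCouplings:
    """Jbar(tau) = J(tau) + eta_tau * sigma_J(tau), eta iid standard normal."""
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(model.T)
    return NoisyCouplings(J_bar=model.J + eta * model.sigma_J, seed=seed)


def convolve_generate(seed_series, couplings: NoisyCouplings, h: float) -> np.ndarray:
    """Slide the coupling window along the seed series; emit N - T modes.

    Output index n (0-based) is sum_tau Jbar(tau) * z[T + n - tau] + h: every
    window is read from the experimental seed series, never from the output,
    so this is a FIR filtering of the seed, not an autoregression.
    """
    z = seed_series.values if hasattr(seed_series, "values") else np.asarray(seed_series, float)
    T = couplings.J_bar.size
    X = design_matrix(z, T)  # raises if N <= T
    return X @ couplings.J_bar + h


def finalize_synthetic(raw: np.ndarray, patient_id: str = "", class_label: str = "UNKNOWN") -> StandardizedSeries:
    """Re-standardize a raw convolution output to zero mean, unit second moment."""
    values, mean, std = standardize_values(np.asarray(raw, dtype=float))
    return StandardizedSeries(
        values=values,
        patient_id=patient_id,
        class_label=class_label,
        mean_ms=mean,
        std_ms=std,
    )
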