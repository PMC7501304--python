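"""Standardization and temporal statistics of RR-interval series.

A raw tachogram r_1..r_N (milliseconds) is mapped onto the dimensionless
series z_n = (r_n - <r>) / std[r], where <r> is the temporal mean and std[r]
the *population* (divisor N) standard deviation.  With this convention the
standardized series has zero mean and unit second moment exactly, so the
lag-0 value of the autocorrelation estimator below is identically 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StandardizedSeries",
    "AutocorrFunction",
    "ClassMoments",
    "standardize",
    "standardize_values",
    "autocorrelation",
    "class_moments",
    "default_tau_max",
]


class DegenerateSeriesError(ValueError):
    """Raised when a series has no variability and cannot be standardized."""


@dataclass(frozen=True)
class StandardizedSeries:
    """Zero-mean, unit-second-moment series plus the inverse-map parameters.

    ``mean_ms`` and ``std_ms`` hold the temporal mean and population standard
    deviation of the source series so that ``values * std_ms + mean_ms``
    recovers the original intervals.
    """

    values: np.ndarray
    patient_id: str = ""
    class_label: str = "UNKNOWN"
    mean_ms: float = 0.0
    std_ms: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("standardized series must be 1-D with N >= 2")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AutocorrFunction:
    """Autocorrelation C(tau) for tau = 0..tau_max."""

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", np.asarray(self.lags, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have matching shapes")


@dataclass(frozen=True)
class ClassMoments:
    """Across-patient averages of the per-series moments within one class."""

    class_label: str
    n_members: int
    mean_z: float
    mean_z2: float
    mean_autocorr: AutocorrFunction = field(repr=False)


def standardize_values(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Return ``(z, mean, std)`` with population-std standardization.

    Raises
    ------
    DegenerateSeriesError
        If the series is constant (zero population standard deviation).
    """
    r = np.asarray(values, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("need a 1-D series with N >= 2")
    mean = float(r.mean())
    std = float(r.std())  # population: divisor N
    # relative threshold: a numerically constant series has std at rounding level
    if not np.isfinite(std) or std <= 1e-12 * max(abs(mean), 1.0):
        raise DegenerateSeriesError("series has (numerically) zero variance; cannot standardize")
    z = (r - mean) / std
    # one exact recentring pass keeps mean(z) at machine zero even for series
    # whose mean is large relative to the fluctuations (e.g. RR in ms)
    z = z - z.mean()
    z = z / np.sqrt(np.mean(z * z))
    return z, mean, std


def standardize(series) -> StandardizedSeries:
    """Standardize an :class:`~glassyhrv.io.RRSeries` (or any object with
    ``intervals``/``patient_id``/``class_label``) to zero mean and unit second
    moment, retaining the original mean/std for inversion."""
    z, mean, std = standardize_values(series.intervals)
    return StandardizedSeries(
        values=z,
        patient_id=getattr(series, "patient_id", ""),
        class_label=getattr(series, "class_label", "UNKNOWN"),
        mean_ms=mean,
        std_ms=std,
    )


def default_tau_max(n: int) -> int:
    """Default autocorrelation window: min(10^4, N/10), at least 1."""
    return max(1, min(10_000, n // 10))


def autocorrelation(z: StandardizedSeries, tau_max: int | None = None) -> AutocorrFunction:
    """Edge-normalized autocorrelation C(tau) = (1/(N-tau)) sum z_n z_{n+tau}.

    The sub-series offset means are *not* subtracted: for a globally
    standardized series they are negligible, and dropping them makes
    C(0) = 1 an exact identity.  Computed via FFT (exact up to roundoff).
    """
    x = z.values if isinstance(z, StandardizedSeries) else np.asarray(z, dtype=float)
    n = x.size
    if tau_max is None:
        tau_max = default_tau_max(n)
    if not 0 <= tau_max < n:
        raise ValueError(f"tau_max must satisfy 0 <= tau_max < N={n}, got {tau_max}")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    raw = np.fft.irfft(spec * np.conj(spec), nfft)[: tau_max + 1]
    lags = np.arange(tau_max + 1)
    values = raw / (n - lags)
    return AutocorrFunction(lags=lags, values=values)


def class_moments(members, tau_max: int) -> ClassMoments:
    """Average <z>, <z^2> and C(tau) over the member series of one class."""
    members = list(members)
    if not members:
        raise ValueError("class_moments requires at least one member series")
    labels = {m.class_label for m in members}
    label = labels.pop() if len(labels) == 1 else "MIXED"
    mean_z = float(np.mean([m.values.mean() for m in members]))
    mean_z2 = float(np.mean([np.mean(m.values**2) for m in members]))
    acfs = [autocorrelation(m, tau_max).values for m in members]
    mean_acf = AutocorrFunction(lags=np.arange(tau_max + 1), values=np.mean(acfs, axis=0))
    return ClassMoments(
        class_label=label,
        n_members=len(members),
        mean_z=mean_z,
        mean_z2=mean_z2,
        mean_autocorr=mean_acf,
    )
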