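"""Ground-truth synthetic cohort generator.

Stands in for the (private) Holter database: plants class-specific glassy
couplings whose magnitudes follow A * tau**-beta with the published per-class
best-fit (A, beta), allows sign-mixed ("frustrated") couplings, samples the
model as a Gaussian autoregression with unit innovations, and wraps the
standardized samples back into physical RR milliseconds.  A separate
frequency-domain fixture provides series with an exactly planted spectral
exponent, independent of the autoregressive machinery.

The model is Gaussian by construction, so the generator reproduces the
correlation structure of real tachograms but not their heavy-tailed
marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from glassyhrv.preprocess import StandardizedSeries, standardize_values

__all__ = [
    "ClassPreset",
    "PlantedModel",
    "CLASS_PRESETS",
    "planted_couplings",
    "sample_autoregressive",
    "make_raw_rr",
    "spectral_shaped_noise",
    "make_dataset",
]

SIGN_SCHEMES = ("random", "alternating", "all_positive")


@dataclass(frozen=True)
class ClassPreset:
    """Per-class generator parameters: power-law couplings plus raw wrapping."""

    class_label: str
    A: float
    beta: float
    n_beats: int = 20_000
    mean_ms: float = 800.0
    std_ms: float = 50.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError("A must be positive")
        if self.mean_ms <= 3 * self.std_ms:
            raise ValueError("mean_ms must exceed 3 * std_ms for positive intervals")


# Published per-class best-fit decay parameters (healthy, atrial fibrillation,
# cardiac decompensation) used as planting presets.
CLASS_PRESETS: dict[str, ClassPreset] = {
    "H": ClassPreset("H", A=0.38, beta=1.41),
    "AF": ClassPreset("AF", A=0.20, beta=0.96),
    "CD": ClassPreset("CD", A=0.37, beta=1.2),
}


@dataclass(frozen=True)
class PlantedModel:
    """Ground-truth couplings with their stationarity bookkeeping."""

    J_true: np.ndarray
    h_true: float
    sign_scheme: str
    rescale_factor: float  # cumulative factor applied to enforce stationarity
    spectral_radius: float

    @property
    def T(self) -> int:
        return self.J_true.size


def ar_spectral_radius(J: np.ndarray) -> float:
    """Spectral radius of the AR companion matrix (max root magnitude of
    x**T - J1 x**(T-1) - ... - JT)."""
    coeffs = np.concatenate(([1.0], -np.asarray(J, dtype=float)))
    roots = np.roots(coeffs)
    return float(np.max(np.abs(roots))) if roots.size else 0.0


def planted_couplings(
    preset: ClassPreset, T: int, sign_scheme: str = "random", seed: int = 0, h: float = 0.0
) -> PlantedModel:
    """Plant |J(tau)| = A * tau**-beta with the requested sign pattern.

    If the resulting autoregression is not stationary (companion spectral
    radius >= 1) the couplings are rescaled by 0.95 / rho repeatedly; the
    cumulative factor is recorded so recovery checks can compare against the
    rescaled truth.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if sign_scheme not in SIGN_SCHEMES:
        raise ValueError(f"sign_scheme must be one of {SIGN_SCHEMES}")
    tau = np.arange(1, T + 1, dtype=float)
    mag = preset.A * tau ** (-preset.beta)
    if sign_scheme == "random":
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=T)
    elif sign_scheme == "alternating":
        signs = np.where(np.arange(T) % 2 == 0, 1.0, -1.0)
    else:
        signs = np.ones(T)
    J = mag * signs
    factor = 1.0
    rho = ar_spectral_radius(J)
    while rho >= 1.0:
        step = 0.95 / rho
        J = J * step
        factor *= step
        rho = ar_spectral_radius(J)
    return PlantedModel(
        J_true=J, h_true=h, sign_scheme=sign_scheme, rescale_factor=factor, spectral_radius=rho
    )


def sample_autoregressive(
    model: PlantedModel, N: int, seed: int, burn_in: int | None = None
) -> StandardizedSeries:
    """Sample z_t = h + sum_tau J(tau) z_{t-tau} + eps_t, eps iid N(0, 1).

    The first ``burn_in`` samples (default 10 T, at least T) are discarded
    and the output is re-standardized.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if model.spectral_radius >= 1.0:
        raise ValueError("autoregression is non-stationary (spectral radius >= 1)")
    T = model.T
    if burn_in is None:
        burn_in = 10 * T
    if burn_in < T:
        raise ValueError("burn_in must be at least T")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(N + burn_in) + model.h_true
    denom = np.concatenate(([1.0], -model.J_true))
    z = signal.lfilter([1.0], denom, eps)[burn_in:]
    values, mean, std = standardize_values(z)
    return StandardizedSeries(values=values, mean_ms=mean, std_ms=std)


def make_raw_rr(z: StandardizedSeries, mean_ms: float, std_ms: float, patient_id: str = "", class_label: str = "UNKNOWN"):
    """Wrap a standardized series into physical RR intervals (milliseconds)."""
    from glassyhrv.io import RRSeries  # local import avoids a cycle

    if mean_ms <= 0 or std_ms <= 0:
        raise ValueError("mean_ms and std_ms must be positive")
    r = z.values * std_ms + mean_ms
    if np.any(r <= 0):
        raise ValueError(
            "wrapping produced nonpositive intervals; use a larger mean_ms or smaller std_ms"
        )
    return RRSeries(patient_id=patient_id, class_label=class_label, intervals=r)


def spectral_shaped_noise(gamma: float, N: int, seed: int) -> StandardizedSeries:
    """Gaussian noise shaped to PSD proportional to f**-gamma, standardized.

    A frequency-domain construction entirely independent of the
    autoregressive sampler; used to validate spectral-exponent estimation
    against a known truth.  N must be a power of two >= 2**10 and gamma in
    [0, 2].
    """
    if not 0.0 <= gamma <= 2.0:
        raise ValueError("gamma must lie in [0, 2]")
    if N < 1024 or (N & (N - 1)) != 0:
        raise ValueError("N must be a power of two, at least 2**10")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(N)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(N, d=1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-gamma / 2.0)
    x = np.fft.irfft(spec * shape, N)
    values, mean, std = standardize_values(x)
    return StandardizedSeries(values=values, mean_ms=mean, std_ms=std)


def make_dataset(
    presets,
    patients_per_class: int,
    N: int,
    T: int,
    seed: int,
    out_dir,
    sign_scheme: str = "random",
):
    """Emit a synthetic cohort: RR text files, manifest CSV and truths JSON.

    Each patient gets fresh planted couplings (class-shared preset,
    per-patient sign seed), one autoregressive sample of N beats, and a raw
    millisecond wrapping.  The planted truths are stored alongside the data
    (``truths.json``) for recovery diagnostics.
    """
    from glassyhrv.io import DatasetManifest, ManifestRecord, write_manifest, write_rr_series

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(presets, dict):
        presets = list(presets.values())
    rng = np.random.default_rng(seed)
    records, truths = [], {}
    for preset in presets:
        for k in range(patients_per_class):
            pid = f"{preset.class_label}{k + 1:03d}"
            sign_seed = int(rng.integers(0, 2**31 - 1))
            sample_seed = int(rng.integers(0, 2**31 - 1))
            planted = planted_couplings(preset, T, sign_scheme, seed=sign_seed)
            z = sample_autoregressive(planted, N, seed=sample_seed)
            rr = make_raw_rr(z, preset.mean_ms, preset.std_ms, pid, preset.class_label)
            path = out_dir / f"{pid}.rr"
            write_rr_series(rr, path)
            records.append(ManifestRecord(patient_id=pid, class_label=preset.class_label, path=path))
            truths[pid] = {
                "J_true": planted.J_true.tolist(),
                "h_true": planted.h_true,
                "rescale_factor": planted.rescale_factor,
                "sign_seed": sign_seed,
                "sample_seed": sample_seed,
            }
    manifest = DatasetManifest(records=tuple(records))
    write_manifest(manifest, out_dir / "manifest.csv")
    (out_dir / "truths.json").write_text(json.dumps(truths, indent=1))
    return manifest
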