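# glassyhrv

Maximum-entropy pairwise ("glassy") modelling of heart-rate variability.

Beat-to-beat fluctuations of RR intervals carry the signature of the
competing sympathetic and parasympathetic drives on the heart.  This
package models a standardized tachogram z₁..z_N as the maximum-entropy
distribution matching its first two moments and two-point correlations —
an exponential family with standard-normal prior, bias h and
distance-dependent pairwise couplings J(τ):

    P(z) ∝ [Π_n P₀(z_n)] · exp( Σ_n Σ_τ J(τ) z_n z_{n+τ} + h Σ_n z_n )

The couplings are inferred by AdaGrad ascent of a regularized Gaussian
pseudo-likelihood with minibatch-resampled uncertainties, their magnitude
decay is summarised by a weighted power-law fit |J(τ)| ~ A·τ^(−β) (the fit
range maximizes the adjusted R²), and the model is validated by
regenerating series by convolution with noisy couplings and comparing
distributions (ECDF bands), autocorrelation (percentile bands) and 1/f
spectra (Welch PSD, PSD ~ α·f^(−γ)).  Couplings of both signs coexist at
the same lag — the frustrated, spin-glass-like structure that motivates
the name.  Since no public Holter cohort exists, a first-class synthetic
generator plants class-specific couplings (healthy, atrial fibrillation,
cardiac decompensation presets) and samples the model autoregressively;
parameter recovery on these planted cohorts is the quantitative surface.

Audience: researchers in physiological time-series analysis and inverse
statistical mechanics who want a tested, reproducible implementation of
pairwise maximum-entropy inference on long autocorrelated series.

## Worked example

```python
import numpy as np
from glassyhrv import (CLASS_PRESETS, PipelineConfig, ResamplingPlan,
                       planted_couplings, sample_autoregressive,
                       resampled_inference, fit_power_law_tail)

preset = CLASS_PRESETS["AF"]                     # A=0.20, beta=0.96
planted = planted_couplings(preset, T=100, sign_scheme="random", seed=101)
series = [sample_autoregressive(planted, 20_000, seed=1000 + k) for k in range(40)]

cfg = PipelineConfig(T=100, n_batches=50, batch_size=8, seed=1)
model = resampled_inference(series, ResamplingPlan(50, 8, seed=1), cfg)
fit = fit_power_law_tail(model)
print(f"beta_hat={fit.beta:.3f}  A_hat={fit.A:.3f}  h={model.h:.2e}")
```

Output:

```
beta_hat=0.993  A_hat=0.200  h=-5.22e-05
```

The recovered exponent 0.993 sits within 0.04 of the planted 0.96 (the
resampling uncertainty band of the fit is wider than that), the amplitude
matches the planted 0.20, and the inferred bias is consistent with zero,
as standardization demands.

## Analysis pipeline

The numbered drivers under `analysis/` run the full study on a simulated
cohort: `01_simulate_cohort.py` (synthetic Holter-style dataset under
`scratch/`), `02_class_statistics.py` (standardization and class moments),
`03_infer_couplings.py`, `04_fit_coupling_tails.py`,
`05_validate_generation.py`, `06_spectral_exponents.py`, and
`07_recovery_benchmark.py`.  Each writes its tables under `results/`.
The same stages are available as a single call,
`glassyhrv.io.run_pipeline(config, manifest, class_label, out_dir)`.

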