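#!/usr/bin/env python
"""Fit the power-law decay of the coupling magnitudes per class.

Reads the inferred couplings, fits |J(tau)| ~ A * tau**-beta by weighted
least squares with the fit range chosen to maximize adjusted R^2, and
reports (A, beta, adjusted R^2, chi^2/DOF) plus normalized residual
diagnostics for each class.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from glassyhrv.model import CouplingModel
from glassyhrv.powerlaw import fit_power_law_tail, normalized_residuals

ROOT = Path(__file__).resolve().parents[1]


def load_model(label: str) -> CouplingModel:
    frame = pd.read_csv(ROOT / "results" / f"couplings_{label}.csv")
    return CouplingModel(
        T=len(frame), J=frame["J"].to_numpy(), h=0.0,
        sigma_J=frame["sigma_J"].to_numpy(), class_label=label,
    )


def main() -> None:
    out = {}
    for label in ("H", "AF", "CD"):
        model = load_model(label)
        fit = fit_power_law_tail(model)
        res = normalized_residuals(fit, model)
        frac_1sigma = float(np.mean(np.abs(res) <= 1.0))
        out[label] = fit.to_dict() | {"residuals_within_1sigma": frac_1sigma}
        print(
            f"class {label}: A={fit.A:.3f}+-{fit.sigma_A:.3f}, "
            f"beta={fit.beta:.3f}+-{fit.sigma_beta:.3f}, "
            f"adj R^2={fit.adj_r2:.3f}, chi^2/DOF={fit.chi2_dof:.2f}, "
            f"{100 * frac_1sigma:.0f}% of residuals within 1 sigma"
        )
    (ROOT / "results" / "powerlaw_fits.json").write_text(json.dumps(out, indent=1))
    print(
        "note: class-mean couplings on a sign-heterogeneous cohort cancel toward "
        "zero, flattening these tails; the quantitative recovery surface is the "
        "shared-couplings benchmark in 07_recovery_benchmark.py"
    )


if __name__ == "__main__":
    main()
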