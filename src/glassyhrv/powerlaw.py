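"""Weighted power-law fit of the coupling-magnitude decay.

The magnitude of the inferred couplings is summarised by
|J(tau)| ~ A * tau**-beta over a tail range [tau_lo, T].  The fit is a
weighted nonlinear least squares on the linear scale with weights
1/sigma_J^2, so that the reduced chi^2 is expressed in units of the stated
per-tau uncertainties; a weighted log-log line provides the starting point.
The lower end of the range is chosen to maximize the adjusted R^2, with
ties broken toward the longest range (smallest tau_lo).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from glassyhrv.model import CouplingModel

__all__ = ["PowerLawFit", "RangeSearch", "fit_power_law_tail", "normalized_residuals"]


@dataclass(frozen=True)
class RangeSearch:
    """Bounds for the tau_lo scan; tau_hi stays pinned at the cutoff T."""

    tau_lo_min: int = 1
    tau_lo_max: int | None = None  # default: T // 2


@dataclass(frozen=True)
class PowerLawFit:
    A: float
    beta: float
    sigma_A: float
    sigma_beta: float
    tau_lo: int
    tau_hi: int
    adj_r2: float
    chi2_dof: float
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "A": self.A,
            "beta": self.beta,
            "sigma_A": self.sigma_A,
            "sigma_beta": self.sigma_beta,
            "tau_lo": self.tau_lo,
            "tau_hi": self.tau_hi,
            "adj_r2": self.adj_r2,
            "chi2_dof": self.chi2_dof,
            "n_excluded": self.n_excluded,
        }


def _power(tau, A, beta):
    return A * tau ** (-beta)


def _weighted_fit(tau, y, sigma):
    """WLS fit of y ~ A * tau**-beta; returns params, covariance, adj R^2, chi2/dof."""
    w = 1.0 / sigma**2
    # log-log weighted line for the starting point (positive values only here)
    ly, lt = np.log(y), np.log(tau)
    lw = w * y**2  # delta(log y) = delta(y) / y
    mean_lt = np.average(lt, weights=lw)
    mean_ly = np.average(ly, weights=lw)
    var_lt = np.average((lt - mean_lt) ** 2, weights=lw)
    slope = 0.0
    if var_lt > 0:
        slope = np.average((lt - mean_lt) * (ly - mean_ly), weights=lw) / var_lt
    p0 = (float(np.exp(mean_ly - slope * mean_lt)), float(-slope))
    popt, pcov = curve_fit(
        _power, tau, y, p0=p0, sigma=sigma, absolute_sigma=True, maxfev=20_000
    )
    yhat = _power(tau, *popt)
    chi2 = float(np.sum(((y - yhat) / sigma) ** 2))
    m = tau.size
    ss_res = float(np.sum(w * (y - yhat) ** 2))
    ss_tot = float(np.sum(w * (y - np.average(y, weights=w)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    adj_r2 = 1.0 - (1.0 - r2) * (m - 1) / (m - 3)  # p = 2 parameters
    return popt, pcov, adj_r2, chi2 / (m - 2)


def fit_power_law_tail(model: CouplingModel, search: RangeSearch | None = None) -> PowerLawFit:
    """Fit |J(tau)| ~ A * tau**-beta on the range maximizing adjusted R^2.

    Candidate ranges are [tau_lo, T] for tau_lo in the search bounds; points
    with |J| exactly zero are excluded (and counted), sigma_J must be
    strictly positive on every used point.  Requires >= 4 usable points in
    at least one candidate range.
    """
    search = search or RangeSearch()
    T = model.T
    tau_lo_max = search.tau_lo_max if search.tau_lo_max is not None else max(1, T // 2)
    tau_all = np.arange(1, T + 1)
    absJ = np.abs(model.J)
    nonzero = absJ > 0
    n_excluded = int(np.count_nonzero(~nonzero))
    if np.any(model.sigma_J[nonzero] <= 0):
        raise ValueError("sigma_J must be strictly positive on all fitted points")

    best = None
    for tau_lo in range(search.tau_lo_min, tau_lo_max + 1):
        keep = nonzero & (tau_all >= tau_lo)
        if np.count_nonzero(keep) < 4:
            continue
        tau = tau_all[keep].astype(float)
        y = absJ[keep]
        sigma = model.sigma_J[keep]
        try:
            popt, pcov, adj_r2, chi2_dof = _weighted_fit(tau, y, sigma)
        except RuntimeError:
            continue
        # strict > keeps the smallest tau_lo (longest range) on ties
        if best is None or adj_r2 > best[0]:
            best = (adj_r2, tau_lo, popt, pcov, chi2_dof)
    if best is None:
        raise ValueError("no candidate range with at least 4 usable points fitted")
    adj_r2, tau_lo, popt, pcov, chi2_dof = best
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    return PowerLawFit(
        A=float(popt[0]),
        beta=float(popt[1]),
        sigma_A=float(perr[0]),
        sigma_beta=float(perr[1]),
        tau_lo=int(tau_lo),
        tau_hi=int(T),
        adj_r2=float(adj_r2),
        chi2_dof=float(chi2_dof),
        n_excluded=n_excluded,
    )


def normalized_residuals(fit: PowerLawFit, model: CouplingModel) -> np.ndarray:
    """(|J(tau)| - A tau**-beta) / sigma_J(tau) over the selected fit range."""
    tau = np.arange(fit.tau_lo, fit.tau_hi + 1)
    absJ = np.abs(model.J[fit.tau_lo - 1 : fit.tau_hi])
    sigma = model.sigma_J[fit.tau_lo - 1 : fit.tau_hi]
    keep = absJ > 0
    if np.any(sigma[keep] == 0):
        raise ValueError("sigma_J vanishes inside the fit range")
    return (absJ[keep] - _power(tau[keep].astype(float), fit.A, fit.beta)) / sigma[keep]
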