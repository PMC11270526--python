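"""Eyring analysis of temperature-dependent dissociation rates.

Transition-state theory relates the dissociation rate constant to the
activation enthalpy and entropy:

    k_d(T) = kappa (k_B T / h) exp(dS / R) exp(-dH / (R T)),

with transmission coefficient ``kappa = 1``.  Linearized,

    ln(k_d / T) = ln(k_B / h) + dS/R - dH/(R T),

so ``dH`` and ``dS`` follow from a straight-line regression of
``ln(k_d/T)`` on ``1/T``.  The module also provides the inverse-variance
weighted combination of several independent ``k_d`` estimates at one
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .constants import H_PLANCK, K_B, R_GAS
from .errors import DomainError, InsufficientDataError

__all__ = [
    "RateSeries",
    "EyringResult",
    "CombinedRate",
    "eyring_fit",
    "eyring_rate",
    "combine_estimates",
]


@dataclass
class RateSeries:
    """Temperature series of dissociation rate constants."""

    T: np.ndarray
    k_d: np.ndarray
    sigma: np.ndarray | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.k_d = np.asarray(self.k_d, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.k_d.shape:
                raise DomainError("sigma and k_d must have equal length")
        if self.T.shape != self.k_d.shape:
            raise DomainError("T and k_d must have equal length")
        if np.any(np.diff(self.T) <= 0):
            raise DomainError("temperatures must be strictly increasing")
        if np.any(self.k_d <= 0):
            raise DomainError("all k_d must be positive")


@dataclass
class EyringResult:
    """Activation parameters: ``dH`` in J/mol, ``dS`` in J/(mol K)."""

    dH: float
    dS: float
    dH_stderr: float
    dS_stderr: float
    covariance: np.ndarray
    kappa: float = 1.0

    def to_dict(self):
        return {
            "dH_kJ_per_mol": self.dH / 1e3,
            "dS_J_per_mol_K": self.dS,
            "dH_stderr_kJ_per_mol": self.dH_stderr / 1e3,
            "dS_stderr_J_per_mol_K": self.dS_stderr,
            "kappa": self.kappa,
        }


@dataclass
class CombinedRate:
    """Inverse-variance weighted mean of several rate estimates."""

    k_d: float
    sigma: float
    inputs: list = field(default_factory=list)

    def to_dict(self):
        return {"k_d": self.k_d, "sigma": self.sigma, "inputs": self.inputs}


def eyring_fit(series: RateSeries, weighted: bool = False) -> EyringResult:
    """Fit the linearized Eyring equation to a rate-temperature series.

    Regression of ``y = ln(k_d/T)`` on ``x = 1/T``: the slope is ``-dH/R``
    and the intercept ``ln(k_B/h) + dS/R``.  With ``weighted=True`` the
    points are weighted by the delta-method uncertainty of ``y``
    (``sigma_y = sigma_k / k_d``); the default is an unweighted fit.
    Requires at least three temperatures.
    """
    if series.T.size < 3:
        raise InsufficientDataError(
            f"Eyring fit needs >= 3 temperatures, got {series.T.size}"
        )
    x = 1.0 / series.T
    y = np.log(series.k_d / series.T)
    X = sm.add_constant(x)
    if weighted:
        if series.sigma is None:
            raise DomainError("weighted fit requested but no sigmas given")
        if np.any(series.sigma <= 0):
            raise DomainError("sigmas must be positive for weighting")
        sy = series.sigma / series.k_d
        res = sm.WLS(y, X, weights=1.0 / sy**2).fit()
    else:
        res = sm.OLS(y, X).fit()
    intercept, slope = res.params
    cov_lin = np.asarray(res.cov_params())
    dH = -slope * R_GAS
    dS = (intercept - np.log(K_B / H_PLANCK)) * R_GAS
    # linear transform (dS, dH) = R_GAS * (intercept - const, -slope)
    Tmat = np.array([[R_GAS, 0.0], [0.0, -R_GAS]])
    cov = Tmat @ cov_lin @ Tmat.T  # order (dS, dH)
    return EyringResult(
        dH=float(dH),
        dS=float(dS),
        dH_stderr=float(np.sqrt(cov[1, 1])),
        dS_stderr=float(np.sqrt(cov[0, 0])),
        covariance=cov,
    )


def eyring_rate(res: EyringResult, T: float) -> float:
    """Forward Eyring prediction ``k_d(T)`` (1/s)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise DomainError("temperature must be positive (Kelvin)")
    out = (
        res.kappa
        * (K_B * T / H_PLANCK)
        * np.exp(res.dS / R_GAS)
        * np.exp(-res.dH / (R_GAS * T))
    )
    return float(out) if out.ndim == 0 else out


def combine_estimates(values, sigmas) -> CombinedRate:
    """Inverse-variance weighted mean with combined standard deviation.

    ``mean = sum(k_i / s_i^2) / sum(1 / s_i^2)``,
    ``sigma = sqrt(1 / sum(1 / s_i^2))``.
    """
    values = np.asarray(values, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    if values.shape != sigmas.shape or values.size < 2:
        raise DomainError("need equal-length lists of >= 2 estimates")
    if np.any(sigmas <= 0):
        raise DomainError("degenerate weight: all sigmas must be positive")
    w = 1.0 / sigmas**2
    mean = float(np.sum(w * values) / np.sum(w))
    comb = float(np.sqrt(1.0 / np.sum(w)))
    return CombinedRate(
        k_d=mean,
        sigma=comb,
        inputs=[{"k_d": float(v), "sigma": float(s)} for v, s in zip(values, sigmas)],
    )
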