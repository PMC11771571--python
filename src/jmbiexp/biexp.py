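"""Bi-exponential nonlinear mixed-effects submodel.

The mean trajectory of a biomarker after a therapy start is

    mu(t) = B * (exp(G t) + exp(-D t) - 1),

with baseline B = mu(0), growth rate G and decay rate D, all positive: the curve
declines under treatment, reaches a nadir at t* = ln(D/G)/(G+D) when D > G, and
regrows afterwards. Subject-level parameters are positive by construction through
the log-scale parameterization B = exp(theta1 + b1), G = exp(theta2 + b2),
D = exp(theta3 + b3) with population means theta and random effects
b ~ N(0, Omega). Measurements carry additive iid Normal(0, sigma^2) error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import BiomarkerSeries

__all__ = [
    "BiExpPopulation",
    "BiExpSubject",
    "subject_params",
    "biexp_mean",
    "nadir_time",
    "longitudinal_loglik",
    "iwres",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class BiExpPopulation:
    """Population parameters of one biomarker's submodel: log-scale means
    ``theta`` (3,), random-effects covariance ``omega`` (3, 3) SPD, and residual
    SD ``sigma`` in g/L."""

    theta: np.ndarray
    omega: np.ndarray
    sigma: float

    def __post_init__(self):
        theta = np.asarray(self.theta, dtype=float).reshape(3)
        omega = np.asarray(self.omega, dtype=float).reshape(3, 3)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "omega", omega)
        if not np.allclose(omega, omega.T):
            raise ValueError("omega must be symmetric")
        if np.any(np.linalg.eigvalsh(omega) <= 0):
            raise ValueError("omega must be positive definite")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class BiExpSubject:
    """Random effects ``b`` (3,) of one subject for one biomarker."""

    b: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float).reshape(3)
        object.__setattr__(self, "b", b)
        if not np.all(np.isfinite(b)):
            raise ValueError("random effects must be finite")


def subject_params(pop: BiExpPopulation, subj: BiExpSubject):
    """Map (theta, b) to the subject's positive (B, G, D)."""
    B, G, D = np.exp(pop.theta + subj.b)
    return float(B), float(G), float(D)


def biexp_mean(B: float, G: float, D: float, t) -> np.ndarray | float:
    """Evaluate mu(t) = B (e^{Gt} + e^{-Dt} - 1) at nonnegative times."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    out = B * (np.exp(G * t) + np.exp(-D * t) - 1.0)
    return out if out.ndim else float(out)


def nadir_time(G: float, D: float) -> float:
    """Time of the trajectory minimum, ln(D/G)/(G+D); defined for D > G > 0."""
    if not (D > G > 0):
        raise ValueError("nadir requires D > G > 0")
    return float(np.log(D / G) / (G + D))


def longitudinal_loglik(
    series: BiomarkerSeries, pop: BiExpPopulation, subj: BiExpSubject
) -> float:
    """Gaussian log-likelihood of one series; an empty series contributes 0."""
    if len(series) == 0:
        return 0.0
    B, G, D = subject_params(pop, subj)
    mu = biexp_mean(B, G, D, series.times)
    resid = series.values - mu
    s2 = pop.sigma**2
    return float(-0.5 * len(series) * (_LOG2PI + np.log(s2)) - 0.5 * np.sum(resid**2) / s2)


def iwres(series: BiomarkerSeries, fitted_values, sigma_hat: float) -> np.ndarray:
    """Individual weighted residuals (y - yhat)/sigma_hat, standard normal under a
    correctly specified model."""
    if not sigma_hat > 0:
        raise ValueError("sigma_hat must be positive")
    fitted = np.asarray(fitted_values, dtype=float)
    if fitted.shape != series.values.shape:
        raise ValueError("fitted values not aligned with series")
    return (series.values - fitted) / sigma_hat
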