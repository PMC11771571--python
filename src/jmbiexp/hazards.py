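"""Cause-specific Weibull proportional hazards sharing log-scale trajectory
parameters.

For event v the hazard is

    h_v(t) = phi_v t^{phi_v - 1} exp(beta0_v) exp(eta_v),
    eta_v  = X' beta_v + sum_k alpha_kv . (B*_k, G*_k, D*_k),

with (B*, G*, D*) the log baseline/growth/decay of biomarker k shared from the
longitudinal submodel. Because the shared terms are time-constant, the
cumulative hazard is closed-form, H_v(t) = exp(beta0_v + eta_v) t^{phi_v};
overall survival multiplies the cause-specific factors,
S(t) = exp(-H_1(t) - H_2(t)). Cumulative incidence integrates h_v S by
Gauss-Legendre quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import SurvivalOutcome

__all__ = [
    "HazardSpec",
    "CompetingRisksModel",
    "linear_predictor",
    "hazard",
    "cumulative_hazard",
    "overall_survival",
    "survival_loglik",
    "cox_snell",
    "cif",
]


@dataclass(frozen=True)
class HazardSpec:
    """One event's parameters: Weibull shape ``phi`` > 0, log-scale intercept
    ``beta0``, covariate coefficients ``beta`` (p,), and association coefficients
    ``alpha`` (K, 3) against each biomarker's (B*, G*, D*)."""

    phi: float
    beta0: float
    beta: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        if not self.phi > 0:
            raise ValueError("phi must be positive")
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.ndim == 1:
            alpha = alpha.reshape(1, -1)
        if alpha.shape[-1] != 3:
            raise ValueError("alpha needs 3 entries (B*, G*, D*) per biomarker")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "alpha", alpha)


@dataclass(frozen=True)
class CompetingRisksModel:
    """One or two cause-specific hazards (v=1 death, v=2 next line of therapy)."""

    events: tuple[HazardSpec, ...]

    def __post_init__(self):
        if len(self.events) not in (1, 2):
            raise ValueError("a block has one or two cause-specific hazards")

    @property
    def n_events(self) -> int:
        return len(self.events)


def _as_logs(subject_logs) -> np.ndarray:
    logs = np.asarray(subject_logs, dtype=float)
    if logs.ndim == 1:
        logs = logs.reshape(1, -1)
    if logs.shape[-1] != 3:
        raise ValueError("subject_logs must hold (B*, G*, D*) triples")
    return logs


def linear_predictor(spec: HazardSpec, X, subject_logs) -> float:
    """eta = X' beta + sum_k alpha_k . (B*_k, G*_k, D*_k)."""
    X = np.atleast_1d(np.asarray(X, dtype=float))
    if X.shape != spec.beta.shape:
        raise ValueError(
            f"design vector has shape {X.shape}, coefficients {spec.beta.shape}"
        )
    logs = _as_logs(subject_logs)
    if logs.shape != spec.alpha.shape:
        raise ValueError(
            f"subject_logs has shape {logs.shape}, alpha {spec.alpha.shape}"
        )
    return float(X @ spec.beta + np.sum(spec.alpha * logs))


def hazard(spec: HazardSpec, X, subject_logs, t) -> np.ndarray | float:
    """Cause-specific hazard h(t) = phi t^{phi-1} e^{beta0 + eta}, t > 0."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("hazard is defined for t > 0")
    eta = linear_predictor(spec, X, subject_logs)
    out = spec.phi * t ** (spec.phi - 1.0) * np.exp(spec.beta0 + eta)
    return out if out.ndim else float(out)


def cumulative_hazard(spec: HazardSpec, X, subject_logs, t) -> np.ndarray | float:
    """Closed form H(t) = e^{beta0 + eta} t^{phi} (the linear predictor is
    time-constant)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("cumulative hazard is defined for t >= 0")
    eta = linear_predictor(spec, X, subject_logs)
    out = np.exp(spec.beta0 + eta) * t**spec.phi
    return out if out.ndim else float(out)


def overall_survival(model: CompetingRisksModel, X, subject_logs, t) -> np.ndarray | float:
    """S(t) = exp(-sum_v H_v(t))."""
    total = sum(cumulative_hazard(spec, X, subject_logs, t) for spec in model.events)
    return np.exp(-np.asarray(total)) if np.ndim(total) else float(np.exp(-total))


def survival_loglik(
    model: CompetingRisksModel, outcome: SurvivalOutcome, X, subject_logs
) -> float:
    """Cause-specific likelihood contribution of one patient:
    log h_v(T) for the observed event v, minus the all-cause cumulative hazard."""
    if outcome.event > model.n_events:
        raise ValueError(
            f"event code {outcome.event} illegal with {model.n_events} event(s)"
        )
    T = outcome.time
    ll = -sum(cumulative_hazard(spec, X, subject_logs, T) for spec in model.events)
    if outcome.event > 0:
        ll += float(np.log(hazard(model.events[outcome.event - 1], X, subject_logs, T)))
    return float(ll)


def cox_snell(model: CompetingRisksModel, outcome: SurvivalOutcome, X, subject_logs) -> float:
    """Cox-Snell residual: the all-cause cumulative hazard at the observed time,
    unit exponential under a correctly specified model."""
    return float(
        sum(cumulative_hazard(spec, X, subject_logs, outcome.time) for spec in model.events)
    )


def cif(
    model: CompetingRisksModel,
    X,
    subject_logs,
    event: int,
    t_from: float,
    u_to,
    quadrature_nodes: int = 30,
) -> np.ndarray | float:
    """Cumulative incidence of ``event`` over (t_from, u_to]:
    integral of h_v(s) S(s) ds by Gauss-Legendre quadrature.

    ``u_to`` may be a scalar or a grid; the result is nonnegative and
    nondecreasing in the horizon.
    """
    if not 1 <= event <= model.n_events:
        raise ValueError(f"event must be in 1..{model.n_events}")
    u = np.asarray(u_to, dtype=float)
    scalar = u.ndim == 0
    u = np.atleast_1d(u)
    if t_from < 0 or np.any(u < t_from):
        raise ValueError("need 0 <= t_from <= u_to")
    nodes, weights = np.polynomial.legendre.leggauss(quadrature_nodes)
    # map (-1, 1) -> (t_from, u) for every horizon at once
    half = (u - t_from) / 2.0
    mid = (u + t_from) / 2.0
    s = mid[:, None] + half[:, None] * nodes[None, :]          # (n_u, n_nodes)
    spec = model.events[event - 1]
    eta = linear_predictor(spec, X, subject_logs)
    s_safe = np.maximum(s, 1e-300)
    h = spec.phi * s_safe ** (spec.phi - 1.0) * np.exp(spec.beta0 + eta)
    H_total = np.zeros_like(s)
    for sp in model.events:
        eta_v = linear_predictor(sp, X, subject_logs)
        H_total += np.exp(sp.beta0 + eta_v) * s_safe ** sp.phi
    integrand = h * np.exp(-H_total)
    out = half * (integrand @ weights)
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out
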