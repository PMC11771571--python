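"""Individual dynamic prediction of conditional cumulative incidence.

For a patient event-free at landmark t with biomarker history y*(<=t) and
baseline covariates X, the conditional probability of event v by horizon u is

    F_v(u, t) = E[ CIF_v(u, t | Theta, b) / S(t | Theta, b) ],

averaged over the posterior of the population parameters Theta and the
patient's random effects b given the history *and* survival to t. The Monte
Carlo scheme per retained draw j: (I) take Theta^(j) from the MCMC sample,
(II) draw b^(j) from pi(b | T > t, history, Theta^(j)) — a short adaptive
random-walk Metropolis chain in the 3K-dimensional b space, warm-started at
the previous draw's state — and (III) evaluate CIF_v(u, t)/S(t) in closed
form plus Gauss-Legendre quadrature. Point estimates are means over draws and
95% bands are Monte Carlo percentiles.

The two-stage variant fixes the longitudinal parameters at their stage-1
plug-ins; only the survival parameters are resampled across draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .biexp import biexp_mean
from .data import BiomarkerSeries
from .hazards import CompetingRisksModel, HazardSpec, cif, overall_survival
from .inference import PluginEstimates
from .mcmc import PosteriorSamples, SurvParams

__all__ = [
    "PatientHistory",
    "DynamicPrediction",
    "DrawState",
    "draw_conditional_random_effects",
    "predict_cif",
    "predict_cif_ts",
    "predict_trajectory",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PatientHistory:
    """A patient's data up to the landmark: one series per biomarker (times on
    the block clock, all <= landmark), the baseline design vector and the
    landmark time in days. The patient is known event-free at the landmark."""

    series: tuple[BiomarkerSeries, ...]
    X: np.ndarray
    landmark: float
    block_id: int = 1

    def __post_init__(self):
        object.__setattr__(self, "X", np.atleast_1d(np.asarray(self.X, dtype=float)))
        if self.landmark < 0:
            raise ValueError("landmark must be nonnegative")
        for s in self.series:
            if len(s) and s.times[-1] > self.landmark:
                raise ValueError("history contains measurements after the landmark")

    @property
    def n_biomarkers(self) -> int:
        return len(self.series)


@dataclass
class DynamicPrediction:
    """Conditional CIF curves per event with pointwise 95% bands."""

    landmark: float
    horizons: np.ndarray
    mean: np.ndarray        # (V, n_u)
    lower: np.ndarray       # (V, n_u)
    upper: np.ndarray       # (V, n_u)
    n_draws: int
    per_draw: np.ndarray | None = None      # (J, V, n_u)
    survival_ratio: np.ndarray | None = None  # (J, n_u): S(u)/S(t) per draw
    attrs: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DrawState:
    """One posterior draw of the block parameters."""

    theta: np.ndarray    # (K, 3)
    omega: np.ndarray    # (K, 3, 3)
    sigma: np.ndarray    # (K,)
    surv: tuple          # tuple[SurvParams, ...]

    def hazard_model(self) -> CompetingRisksModel:
        return CompetingRisksModel(tuple(
            HazardSpec(phi=float(np.exp(s.log_phi)), beta0=s.beta0,
                       beta=s.beta, alpha=s.alpha)
            for s in self.surv
        ))


def _states_from_samples(samples: PosteriorSamples,
                         plugins: PluginEstimates | None = None):
    """Indexable draw accessor; with plug-ins given, the longitudinal block is
    fixed and only survival parameters vary across draws (two-stage path)."""
    phi = samples.stacked("phi")
    beta0 = samples.stacked("beta0")
    V = phi.shape[1]
    betas = [samples.stacked(f"beta{v + 1}") if f"beta{v + 1}" in samples.draws else None
             for v in range(V)]
    alphas = [samples.stacked(f"alpha{v + 1}") for v in range(V)]
    if plugins is None:
        theta = samples.stacked("theta")
        omega = samples.stacked("omega")
        sigma = samples.stacked("sigma")
    total = phi.shape[0]

    def get(j: int) -> DrawState:
        surv = tuple(
            SurvParams(
                log_phi=float(np.log(phi[j, v])),
                beta0=float(beta0[j, v]),
                beta=betas[v][j] if betas[v] is not None else np.zeros(0),
                alpha=alphas[v][j],
            )
            for v in range(V)
        )
        if plugins is None:
            return DrawState(theta[j], omega[j], sigma[j], surv)
        return DrawState(plugins.theta, plugins.omega, plugins.sigma, surv)

    return get, total


def _conditional_logpost(history: PatientHistory, state: DrawState,
                         b: np.ndarray, model: CompetingRisksModel | None,
                         omega_chol: Sequence[np.ndarray]) -> float:
    """log pi(b | T > t, history, Theta) up to a constant; ``model=None`` drops
    the survival-to-t factor (the longitudinal-only conditional)."""
    K = history.n_biomarkers
    total = 0.0
    for k in range(K):
        bk = b[k]
        L = omega_chol[k]
        z = np.linalg.solve(L, bk)
        total += -0.5 * float(z @ z)
        s = history.series[k]
        if len(s):
            logs = state.theta[k] + bk
            with np.errstate(over="ignore", invalid="ignore"):
                B, G, D = np.exp(logs)
                mu = B * (np.exp(G * s.times) + np.exp(-D * s.times) - 1.0)
                ss = float(np.sum((s.values - mu) ** 2))
            if not np.isfinite(ss):
                return -np.inf
            sig2 = state.sigma[k] ** 2
            total += -0.5 * len(s) * (_LOG2PI + np.log(sig2)) - 0.5 * ss / sig2
    if model is not None and history.landmark > 0:
        logs_stack = state.theta + b   # (K, 3)
        H = 0.0
        for spec in model.events:
            eta = float(history.X @ spec.beta + np.sum(spec.alpha * logs_stack))
            with np.errstate(over="ignore"):
                H += np.exp(spec.beta0 + eta) * history.landmark ** spec.phi
        if not np.isfinite(H):
            return -np.inf
        total -= H
    return total


def draw_conditional_random_effects(
    history: PatientHistory,
    theta_draw: DrawState,
    rng,
    n_adapt: int = 50,
    n_iter: int = 50,
    init: np.ndarray | None = None,
    include_survival: bool = True,
):
    """One draw from pi(b | T > t, history, Theta) by short adaptive
    random-walk Metropolis; returns (b, final proposal scales)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    K = history.n_biomarkers
    use_surv = include_survival and bool(theta_draw.surv)
    model = theta_draw.hazard_model() if use_surv else None
    chol = [np.linalg.cholesky(theta_draw.omega[k]) for k in range(K)]
    b = init.copy() if init is not None else np.zeros((K, 3))

    def logpost(bb):
        return _conditional_logpost(history, theta_draw, bb, model, chol)

    cur = logpost(b)
    log_scales = np.full(K, np.log(0.8))
    for it in range(n_adapt + n_iter):
        for k in range(K):
            prop = b.copy()
            prop[k] = b[k] + np.exp(log_scales[k]) * (chol[k] @ rng.standard_normal(3))
            cand = logpost(prop)
            acc = np.log(rng.uniform()) < cand - cur
            if acc:
                b, cur = prop, cand
            if it < n_adapt:
                log_scales[k] += (it + 1) ** -0.6 * (float(acc) - 0.3)
    return b, np.exp(log_scales)


def _predict_from_states(history, get_state, total, horizons, J, seed,
                         quadrature_nodes, conditional_iters):
    rng = np.random.default_rng(seed)
    horizons = np.atleast_1d(np.asarray(horizons, dtype=float))
    if np.any(horizons < history.landmark):
        raise ValueError("horizons must not precede the landmark")
    if J < 1:
        raise ValueError("J must be >= 1")
    if J >= total:
        idx = np.arange(total)
    else:
        idx = np.sort(rng.choice(total, size=J, replace=False))
    J_eff = idx.size
    n_adapt, n_iter = conditional_iters
    t = history.landmark

    first = get_state(int(idx[0]))
    V = len(first.surv)
    F = np.empty((J_eff, V, horizons.size))
    S_ratio = np.empty((J_eff, horizons.size))
    b_prev = None
    for jj, j in enumerate(idx):
        state = get_state(int(j))
        b, _ = draw_conditional_random_effects(
            history, state, rng, n_adapt=n_adapt, n_iter=n_iter, init=b_prev)
        b_prev = b
        logs = state.theta + b
        model = state.hazard_model()
        St = overall_survival(model, history.X, logs, t) if t > 0 else 1.0
        Su = overall_survival(model, history.X, logs, horizons)
        S_ratio[jj] = np.atleast_1d(Su) / St
        for v in range(V):
            F[jj, v] = cif(model, history.X, logs, v + 1, t, horizons,
                           quadrature_nodes=quadrature_nodes) / St
    mean = F.mean(axis=0)
    lower = np.percentile(F, 2.5, axis=0)
    upper = np.percentile(F, 97.5, axis=0)
    return DynamicPrediction(landmark=t, horizons=horizons, mean=mean,
                             lower=lower, upper=upper, n_draws=J_eff,
                             per_draw=F, survival_ratio=S_ratio)


def predict_cif(
    history: PatientHistory,
    samples: PosteriorSamples,
    horizons,
    J: int | None = None,
    seed: int = 0,
    quadrature_nodes: int = 30,
    conditional_iters: tuple[int, int] = (50, 50),
) -> DynamicPrediction:
    """Joint-estimation dynamic prediction: average CIF_v(u,t)/S(t) over
    posterior draws of all parameters and conditional random-effects draws."""
    get_state, total = _states_from_samples(samples)
    if J is None:
        J = total
    return _predict_from_states(history, get_state, total, horizons, J, seed,
                                quadrature_nodes, conditional_iters)


def predict_cif_ts(
    history: PatientHistory,
    stage2_samples: PosteriorSamples,
    plugins: PluginEstimates,
    horizons,
    J: int | None = None,
    seed: int = 0,
    quadrature_nodes: int = 30,
    conditional_iters: tuple[int, int] = (50, 50),
) -> DynamicPrediction:
    """Two-stage dynamic prediction: longitudinal parameters fixed at their
    stage-1 plug-ins; survival parameters drawn from the stage-2 posterior."""
    get_state, total = _states_from_samples(stage2_samples, plugins=plugins)
    if J is None:
        J = total
    return _predict_from_states(history, get_state, total, horizons, J, seed,
                                quadrature_nodes, conditional_iters)


def predict_trajectory(
    history: PatientHistory,
    samples: PosteriorSamples,
    time_grid,
    J: int | None = None,
    seed: int = 0,
    plugins: PluginEstimates | None = None,
    conditional_iters: tuple[int, int] = (50, 50),
):
    """Posterior-updated biomarker trajectories: pointwise mean and 95% band of
    mu(t) over draws of (Theta, b | history, T > t).

    Returns a dict biomarker index -> array (4, n_grid): time, mean, lower,
    upper.
    """
    rng = np.random.default_rng(seed)
    grid = np.atleast_1d(np.asarray(time_grid, dtype=float))
    get_state, total = _states_from_samples(samples, plugins=plugins)
    if J is None:
        J = total
    idx = np.arange(total) if J >= total else np.sort(
        rng.choice(total, size=J, replace=False))
    n_adapt, n_iter = conditional_iters
    K = history.n_biomarkers
    curves = np.empty((idx.size, K, grid.size))
    b_prev = None
    for jj, j in enumerate(idx):
        state = get_state(int(j))
        b, _ = draw_conditional_random_effects(
            history, state, rng, n_adapt=n_adapt, n_iter=n_iter, init=b_prev)
        b_prev = b
        for k in range(K):
            B, G, D = np.exp(state.theta[k] + b[k])
            curves[jj, k] = biexp_mean(B, G, D, grid)
    out = {}
    for k in range(K):
        out[history.series[k].biomarker_id if k < len(history.series) else k] = np.vstack([
            grid,
            curves[:, k, :].mean(axis=0),
            np.percentile(curves[:, k, :], 2.5, axis=0),
            np.percentile(curves[:, k, :], 97.5, axis=0),
        ])
    return out
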