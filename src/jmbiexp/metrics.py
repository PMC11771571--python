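"""Out-of-sample validation: discrimination and calibration under competing
risks and right-censoring.

* ``td_auc_ipcw`` — cumulative-case / dynamic-control time-dependent AUC at a
  landmark. Cases experience the indexed event inside (t, t+dt]; controls are
  event-free past t+dt or experienced the *competing* event by then; subjects
  censored inside the window drop out and the loss is compensated by inverse
  probability of censoring weights from a Kaplan-Meier fit of the censoring
  distribution on the at-risk set. Ties in predicted risk count 1/2. With no
  censoring the estimator reduces exactly to the empirical AUC.
* ``calibration_table`` — quantile groups of predicted risk against the
  Aalen-Johansen cumulative incidence observed within each group (1 - KM would
  overstate cause-specific risk when competing events remove patients).
* ``cox_snell_check`` — Kaplan-Meier survival curve of Cox-Snell residuals
  compared with the unit exponential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RiskPredictionSet",
    "CalibrationTable",
    "UndefinedMetricError",
    "td_auc_ipcw",
    "calibration_table",
    "cox_snell_check",
]


class UndefinedMetricError(ValueError):
    """No cases or no controls remain after windowing/weighting."""


@dataclass(frozen=True)
class RiskPredictionSet:
    """Predicted risks F_v(t+dt, t) with observed outcomes on the block clock.

    All patients are event-free at the landmark ``t``; ``time``/``event`` are
    the observed outcome (0 censored, 1.. event codes); ``predicted`` holds the
    conditional risk of the indexed event by ``t + dt``.
    """

    predicted: np.ndarray
    time: np.ndarray
    event: np.ndarray
    landmark: float
    horizon: float

    def __post_init__(self):
        pred = np.asarray(self.predicted, dtype=float)
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event, dtype=int)
        if not (pred.shape == time.shape == event.shape):
            raise ValueError("prediction/outcome arrays must be aligned")
        if np.any((pred < 0) | (pred > 1)):
            raise ValueError("predicted risks must lie in [0, 1]")
        if np.any(time <= self.landmark):
            raise ValueError("all patients must be event-free at the landmark")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        object.__setattr__(self, "predicted", pred)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event)

    @property
    def n(self) -> int:
        return self.predicted.size


@dataclass(frozen=True)
class CalibrationTable:
    """Per risk-group mean predicted vs Aalen-Johansen observed risk."""

    table: pd.DataFrame   # columns: group, n, predicted, observed, observed_se
    event: int
    landmark: float
    horizon: float


def _censoring_km(times: np.ndarray, censored: np.ndarray):
    """Kaplan-Meier of the censoring distribution; returns a step evaluator
    G(x) = P(C > x) on the landmark clock."""
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    c_sorted = censored[order]
    uniq = np.unique(t_sorted[c_sorted])
    n = times.size
    surv = []
    g = 1.0
    for u in uniq:
        at_risk = np.sum(t_sorted >= u)
        d = np.sum((t_sorted == u) & c_sorted)
        if at_risk > 0:
            g *= 1.0 - d / at_risk
        surv.append(g)
    surv = np.asarray(surv)

    def G(x):
        x = np.asarray(x, dtype=float)
        idx = np.searchsorted(uniq, x, side="right") - 1
        out = np.where(idx >= 0, surv[np.clip(idx, 0, None)], 1.0)
        return out if out.ndim else float(out)

    return G


def td_auc_ipcw(preds: RiskPredictionSet, event: int = 1) -> float:
    """IPCW cumulative/dynamic AUC for ``event`` over (t, t+dt]."""
    t, dt = preds.landmark, preds.horizon
    rel = preds.time - t                      # time on the landmark clock
    cases = (rel <= dt) & (preds.event == event)
    competing = (rel <= dt) & (preds.event != event) & (preds.event != 0)
    beyond = rel > dt
    controls = beyond | competing
    if not cases.any() or not controls.any():
        raise UndefinedMetricError("need at least one case and one control")

    G = _censoring_km(rel, preds.event == 0)
    w = np.zeros(preds.n)
    # cases and competing-event controls: weight by G just before their time;
    # event-free controls: by G at the horizon
    g_case = G(np.maximum(rel[cases] - 1e-12, 0.0))
    g_comp = G(np.maximum(rel[competing] - 1e-12, 0.0))
    g_h = G(dt)
    with np.errstate(divide="ignore"):
        w[cases] = np.where(g_case > 0, 1.0 / g_case, 0.0)
        w[competing] = np.where(g_comp > 0, 1.0 / g_comp, 0.0)
        w[beyond] = 1.0 / g_h if g_h > 0 else 0.0
    if w[cases].sum() == 0 or w[controls].sum() == 0:
        raise UndefinedMetricError("all case or control weight vanished")

    p_case, w_case = preds.predicted[cases], w[cases]
    p_ctrl, w_ctrl = preds.predicted[controls], w[controls]
    diff = p_case[:, None] - p_ctrl[None, :]
    kernel = (diff > 0) + 0.5 * (diff == 0)
    weight = w_case[:, None] * w_ctrl[None, :]
    return float(np.sum(kernel * weight) / np.sum(weight))


def _aalen_johansen_at(durations, events, event: int, horizon: float) -> tuple[float, float]:
    """Aalen-Johansen cumulative incidence of ``event`` at ``horizon`` with a
    Greenwood-style standard error via lifelines."""
    from lifelines import AalenJohansenFitter

    if not np.any(events == event):
        return 0.0, 0.0
    ajf = AalenJohansenFitter(calculate_variance=True)
    ajf.fit(durations, events, event_of_interest=event)
    cd = ajf.cumulative_density_
    times = cd.index.to_numpy(dtype=float)
    vals = cd.iloc[:, 0].to_numpy(dtype=float)
    idx = np.searchsorted(times, horizon, side="right") - 1
    est = float(vals[idx]) if idx >= 0 else 0.0
    se = 0.0
    if ajf.variance_ is not None and idx >= 0:
        var = ajf.variance_.to_numpy(dtype=float).ravel()
        se = float(np.sqrt(max(var[min(idx, var.size - 1)], 0.0)))
    return est, se


def calibration_table(preds: RiskPredictionSet, event: int = 1,
                      n_groups: int = 3) -> CalibrationTable:
    """Group patients by quantiles of predicted risk and compare the group mean
    prediction with the Aalen-Johansen observed cumulative incidence at the
    horizon."""
    if n_groups < 2:
        raise ValueError("need at least 2 risk groups")
    if preds.n // n_groups < 2:
        raise ValueError(
            f"{preds.n} patients cannot fill {n_groups} groups; use fewer groups"
        )
    ranks = pd.Series(preds.predicted).rank(method="first")
    groups = pd.qcut(ranks, n_groups, labels=False)
    rel = preds.time - preds.landmark
    rows = []
    for g in range(n_groups):
        m = (groups == g).to_numpy()
        if m.sum() == 0:
            raise ValueError("empty risk group after binning; use fewer groups")
        obs, se = _aalen_johansen_at(rel[m], preds.event[m], event, preds.horizon)
        rows.append({
            "group": g,
            "n": int(m.sum()),
            "predicted": float(preds.predicted[m].mean()),
            "observed": obs,
            "observed_se": se,
        })
    table = pd.DataFrame(rows).sort_values("predicted").reset_index(drop=True)
    table["group"] = np.arange(n_groups)
    return CalibrationTable(table=table, event=event,
                            landmark=preds.landmark, horizon=preds.horizon)


def cox_snell_check(residuals, censor_flags=None) -> dict:
    """Compare the Kaplan-Meier curve of Cox-Snell residuals with exp(-x).

    Returns the maximal absolute deviation over the KM support and flags
    uninformative input (no observed events).
    """
    from lifelines import KaplanMeierFitter

    r = np.asarray(residuals, dtype=float)
    if np.any(r < 0):
        raise ValueError("Cox-Snell residuals must be nonnegative")
    observed = np.ones_like(r, dtype=bool) if censor_flags is None \
        else np.asarray(censor_flags, dtype=bool)
    if not observed.any():
        return {"max_deviation": np.nan, "n_events": 0, "informative": False}
    kmf = KaplanMeierFitter()
    kmf.fit(r, event_observed=observed)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    km = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    dev = np.abs(km[keep] - np.exp(-times[keep]))
    return {
        "max_deviation": float(dev.max()) if dev.size else 0.0,
        "n_events": int(observed.sum()),
        "informative": True,
    }
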