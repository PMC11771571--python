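"""Synthetic multiple-myeloma-like block generator with known truth.

Each simulated block mimics the structure of a line-of-therapy (LoT) cohort:
two biomarkers (an M-spike-like paraprotein and an FLC-like light chain, g/L)
with decline-then-regrowth bi-exponential trajectories and irregular visit
schedules, mixed baseline covariates with missing values, and two competing
events (death, transition to the next LoT) plus administrative and random
censoring. Latent cause-specific event times are drawn by inverting each
Weibull cause-specific cumulative hazard — a valid device because the
cause-specific hazards fully determine the observed-data likelihood; the
independence of the latent times is not an identifiable assumption.

The default truth targets the event mix of a first-line cohort (~15% death,
~51% transition, ~34% censored, with median block times of a few hundred
days); these are calibration targets of the generator, not claims about any
particular dataset. Chained blocks reset the clock at each LoT start: the
patients who transition form the next block's population with fresh random
effects, and the time spent in the previous LoT enters the next block's
hazards as a covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biexp import BiExpPopulation
from .data import (BiomarkerSeries, BlockDataset, CovariateTable,
                   SurvivalOutcome)
from .hazards import HazardSpec

__all__ = [
    "ContinuousCovariate",
    "CategoricalCovariate",
    "VisitSchedule",
    "CensoringSpec",
    "SimulationTruth",
    "SimulatedBlock",
    "simulate_event_time",
    "simulate_block",
    "simulate_study",
    "default_truth",
    "default_study_truths",
]


@dataclass(frozen=True)
class ContinuousCovariate:
    """Generator for one continuous baseline covariate. The hazard acts on the
    standardized latent Z; the emitted raw value is ``mean + sd * Z`` (or
    ``exp(mean + sd * Z)`` when lognormal) with MCAR missingness."""

    name: str
    mean: float
    sd: float
    lognormal: bool = False
    missing_rate: float = 0.0


@dataclass(frozen=True)
class CategoricalCovariate:
    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    missing_rate: float = 0.0

    def __post_init__(self):
        if len(self.levels) != len(self.probs):
            raise ValueError("levels and probs must align")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")


@dataclass(frozen=True)
class VisitSchedule:
    """First visit at t=0, then gamma-distributed gaps truncated at the
    observed time."""

    mean_gap: float = 30.0
    shape: float = 2.0


@dataclass(frozen=True)
class CensoringSpec:
    horizon: float = 730.0       # administrative, days
    rate: float = 0.0012         # exponential random censoring, per day

    def __post_init__(self):
        if self.horizon <= 0:
            raise ValueError("administrative horizon must be positive")


@dataclass(frozen=True)
class SimulationTruth:
    """Complete generative specification of one block."""

    biomarkers: tuple[BiExpPopulation, ...]
    events: tuple[HazardSpec, ...]
    continuous: tuple[ContinuousCovariate, ...] = ()
    categorical: tuple[CategoricalCovariate, ...] = ()
    visits: VisitSchedule = field(default_factory=VisitSchedule)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    n_patients: int = 250
    block_id: int = 1

    def __post_init__(self):
        p = self.n_design_columns
        for spec in self.events:
            if spec.beta.size != p:
                raise ValueError(
                    f"hazard beta has {spec.beta.size} entries, design has {p}")
            if spec.alpha.shape[0] != len(self.biomarkers):
                raise ValueError("alpha rows must match the number of biomarkers")

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def design_columns(self) -> tuple[str, ...]:
        cols = [c.name for c in self.continuous]
        for c in self.categorical:
            cols.extend(f"{c.name}_{lev}" for lev in c.levels[1:])
        return tuple(cols)

    @property
    def n_design_columns(self) -> int:
        return len(self.design_columns)


@dataclass(frozen=True)
class SimulatedBlock:
    """A BlockDataset plus the latent truth that produced it."""

    dataset: BlockDataset
    b: np.ndarray                 # (K, n, 3)
    design: np.ndarray            # (n, p) true standardized design
    latent_times: np.ndarray      # (n, V)
    censor_times: np.ndarray      # (n,)
    truth: SimulationTruth


def simulate_event_time(spec: HazardSpec, X, subject_logs, u) -> float | np.ndarray:
    """Invert the Weibull cause-specific cumulative hazard at uniform draw u:
    T = (-log u / exp(beta0 + eta))^(1/phi)."""
    from .hazards import linear_predictor

    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie in (0, 1)")
    eta = linear_predictor(spec, X, subject_logs)
    out = (-np.log(u) / np.exp(spec.beta0 + eta)) ** (1.0 / spec.phi)
    return out if out.ndim else float(out)


def _draw_covariates(truth: SimulationTruth, n: int, rng):
    """Returns (raw frame dict with missingness, true standardized design (n, p))."""
    raw = {}
    design_cols = []
    for c in truth.continuous:
        z = rng.standard_normal(n)
        value = np.exp(c.mean + c.sd * z) if c.lognormal else c.mean + c.sd * z
        miss = rng.uniform(size=n) < c.missing_rate
        raw[c.name] = np.where(miss, np.nan, value)
        design_cols.append(z)
    for c in truth.categorical:
        draw = rng.choice(len(c.levels), size=n, p=np.asarray(c.probs))
        labels = np.asarray(c.levels, dtype=object)[draw]
        miss = rng.uniform(size=n) < c.missing_rate
        labels = np.where(miss, None, labels)
        raw[c.name] = labels
        for j in range(1, len(c.levels)):
            design_cols.append((draw == j).astype(float))
    design = np.column_stack(design_cols) if design_cols else np.zeros((n, 0))
    return raw, design


def simulate_block(truth: SimulationTruth, seed: int,
                   patient_ids=None,
                   extra_design: np.ndarray | None = None,
                   extra_raw: pd.DataFrame | None = None,
                   include_longitudinal: bool = True) -> SimulatedBlock:
    """Draw one block: covariates -> random effects -> latent cause-specific
    times -> observed (T, delta) -> biomarker visits with Gaussian noise."""
    rng = np.random.default_rng(seed)
    n = truth.n_patients
    K = len(truth.biomarkers)
    V = truth.n_events
    if patient_ids is None:
        patient_ids = [f"P{i + 1:05d}" for i in range(n)]

    if extra_design is not None:
        # chained block: covariates are carried over verbatim, never redrawn
        if extra_raw is None:
            raise ValueError("extra_design requires the matching raw table")
        raw, design = None, extra_design
    else:
        raw, design = _draw_covariates(truth, n, rng)
    if design.shape[1] != truth.n_design_columns:
        raise ValueError("design width does not match truth specification")

    b = np.empty((K, n, 3))
    for k, pop in enumerate(truth.biomarkers):
        L = np.linalg.cholesky(pop.omega)
        b[k] = rng.standard_normal((n, 3)) @ L.T
    logs = np.stack([pop.theta for pop in truth.biomarkers])[:, None, :] + b  # (K,n,3)

    latent = np.empty((n, V))
    for v, spec in enumerate(truth.events):
        shared = np.tensordot(logs, spec.alpha, axes=([0, 2], [0, 1]))
        eta = design @ spec.beta + shared
        u = rng.uniform(size=n)
        latent[:, v] = (-np.log(u) / np.exp(spec.beta0 + eta)) ** (1.0 / spec.phi)

    censor = np.full(n, truth.censoring.horizon)
    if truth.censoring.rate > 0:
        censor = np.minimum(censor, rng.exponential(1.0 / truth.censoring.rate, size=n))

    T = np.minimum(latent.min(axis=1), censor)
    delta = np.where(latent.min(axis=1) <= censor, latent.argmin(axis=1) + 1, 0)
    T = np.maximum(T, 1e-8)

    series = []
    if include_longitudinal:
        gap_shape = truth.visits.shape
        gap_scale = truth.visits.mean_gap / gap_shape
        # enough candidate gaps to exceed the longest follow-up with margin
        m = int(np.ceil(T.max() / truth.visits.mean_gap * 2.5)) + 10
        for k, pop in enumerate(truth.biomarkers):
            gaps = rng.gamma(gap_shape, gap_scale, size=(n, m))
            visit_times = np.cumsum(gaps, axis=1)
            B, G, D = (np.exp(logs[k, :, c])[:, None] for c in range(3))
            for i in range(n):
                times = np.concatenate([[0.0], visit_times[i][visit_times[i] <= T[i]]])
                mu = B[i, 0] * (np.exp(G[i, 0] * times) + np.exp(-D[i, 0] * times) - 1.0)
                values = mu + pop.sigma * rng.standard_normal(times.size)
                series.append(BiomarkerSeries(patient_ids[i], k + 1, times, values))

    outcomes = tuple(SurvivalOutcome(patient_ids[i], float(T[i]), int(delta[i]))
                     for i in range(n))
    if raw is not None:
        frame = pd.DataFrame(raw, index=pd.Index(patient_ids, name="patient_id"))
    else:
        frame = extra_raw.copy()
        frame.index = pd.Index(patient_ids, name="patient_id")
    cont_names = tuple(c for c in frame.columns
                       if c not in {c2.name for c2 in truth.categorical})
    covariates = CovariateTable(frame, continuous=cont_names,
                                categorical=tuple(c.name for c in truth.categorical))
    dataset = BlockDataset(block_id=truth.block_id, series=tuple(series),
                           outcomes=outcomes, covariates=covariates,
                           n_events=V)
    return SimulatedBlock(dataset=dataset, b=b, design=design,
                          latent_times=latent, censor_times=censor, truth=truth)


def simulate_study(truths, seed: int) -> list[SimulatedBlock]:
    """Chained blocks with clock reset: block l+1's population is exactly the
    set of block-l patients with event 2, carrying their observed block-l time
    as the covariate ``prev_lot_days``. The final block must be single-event."""
    truths = list(truths)
    if truths[-1].n_events != 1:
        raise ValueError("the final block must model death only (single event)")
    rng = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in rng.spawn(len(truths))]

    blocks = [simulate_block(replace(truths[0], block_id=1), seeds[0])]
    for l in range(1, len(truths)):
        prev = blocks[-1]
        cont_mask = np.array([o.event == 2 for o in prev.dataset.outcomes])
        cont_ids = [o.patient_id for o in prev.dataset.outcomes if o.event == 2]
        if not cont_ids:
            warnings.warn(f"no patients transitioned into block {l + 1}; study truncated")
            break
        prev_T = np.array([o.time for o in prev.dataset.outcomes if o.event == 2])
        # previous-LoT time enters the hazard standardized on the log scale
        prev_z = (np.log(prev_T) - np.log(230.0)) / 0.6
        carried_raw = prev.dataset.covariates.frame.loc[cont_ids].copy()
        prev_design = prev.design[cont_mask]
        if "prev_lot_days" in carried_raw.columns:
            # replace the previous block's own carry-over column
            carried_raw = carried_raw.drop(columns=["prev_lot_days"])
            prev_design = prev_design[:, 1:]
        carried_raw.insert(0, "prev_lot_days", prev_T)
        carried_design = np.column_stack([prev_z, prev_design])
        truth_l = replace(truths[l], n_patients=len(cont_ids), block_id=l + 1)
        blk = simulate_block(truth_l, seeds[l], patient_ids=cont_ids,
                             extra_design=carried_design, extra_raw=carried_raw)
        blocks.append(blk)
    return blocks


# ---------------------------------------------------------------------------
# default truth: a first-line-like cohort
# ---------------------------------------------------------------------------

_DEATH, _NEXT = 0, 1


def _calibrated_beta0(phi: float, target_rate: float, expected_eta: float,
                      t_ref: float = 230.0) -> float:
    """Choose beta0 so the cause's cumulative hazard at the reference time
    equals target_rate * t_ref for an average subject."""
    return float(np.log(target_rate) + (1.0 - phi) * np.log(t_ref) - expected_eta)


def default_truth(n_patients: int = 250, n_events: int = 2,
                  include_prev_lot: bool = False) -> SimulationTruth:
    """First-line-like block: two biomarkers, three baseline covariates, two
    competing events with an event mix targeting ~15% death / ~51% transition /
    ~34% censored over a two-year administrative window."""
    biomarkers = (
        BiExpPopulation(theta=np.log([25.0, 0.0015, 0.02]),
                        omega=np.array([[0.16, 0.01, 0.01],
                                        [0.01, 0.25, 0.01],
                                        [0.01, 0.01, 0.25]]),
                        sigma=1.0),
        BiExpPopulation(theta=np.log([4.0, 0.002, 0.015]),
                        omega=np.array([[0.16, 0.01, 0.01],
                                        [0.01, 0.25, 0.01],
                                        [0.01, 0.01, 0.25]]),
                        sigma=0.35),
    )
    continuous = [
        ContinuousCovariate("age", mean=65.0, sd=10.0),
        ContinuousCovariate("albumin", mean=3.5, sd=0.25, lognormal=True,
                            missing_rate=0.15),
    ]
    if include_prev_lot:
        continuous = [ContinuousCovariate("prev_lot_days", 0.0, 1.0)] + continuous
    categorical = (CategoricalCovariate("ecog", ("0-1", "2+"), (0.7, 0.3),
                                        missing_rate=0.05),)

    beta_death = np.array([0.4, -0.25, 0.5])
    beta_next = np.array([-0.2, 0.1, 0.2])
    if include_prev_lot:
        beta_death = np.concatenate([[0.1], beta_death])
        beta_next = np.concatenate([[-0.3], beta_next])
    alpha_death = np.array([[0.3, 0.15, 0.0], [0.2, 0.0, 0.0]])
    alpha_next = np.array([[0.25, 0.3, 0.0], [0.15, 0.2, 0.0]])
    phi_death, phi_next = 0.9, 1.1

    ind_mean = np.array([p for c in categorical for p in c.probs[1:]])
    theta_stack = np.stack([p.theta for p in biomarkers])
    n_cont = len(continuous)

    def expected_eta(beta, alpha):
        """Mean of eta plus half its variance, so that E[exp(eta)] is matched
        (eta is approximately Gaussian across subjects)."""
        cat_part = float(beta[-ind_mean.size:] @ ind_mean) if ind_mean.size else 0.0
        mean = cat_part + float(np.sum(alpha * theta_stack))
        var = float(np.sum(beta[:n_cont] ** 2))  # standardized continuous, var 1
        if ind_mean.size:
            var += float(np.sum(beta[-ind_mean.size:] ** 2 * ind_mean * (1 - ind_mean)))
        for k, pop in enumerate(biomarkers):
            var += float(alpha[k] @ pop.omega @ alpha[k])
        return mean + 0.5 * var

    target_death, target_next = 0.00068, 0.0023
    events = [
        HazardSpec(phi=phi_death,
                   beta0=_calibrated_beta0(phi_death, target_death,
                                           expected_eta(beta_death, alpha_death)),
                   beta=beta_death, alpha=alpha_death),
    ]
    if n_events == 2:
        events.append(
            HazardSpec(phi=phi_next,
                       beta0=_calibrated_beta0(phi_next, target_next,
                                               expected_eta(beta_next, alpha_next)),
                       beta=beta_next, alpha=alpha_next))
    return SimulationTruth(
        biomarkers=biomarkers,
        events=tuple(events),
        continuous=tuple(continuous),
        categorical=categorical,
        n_patients=n_patients,
    )


def default_study_truths(n_patients: int = 250, n_blocks: int = 3):
    """Chained-study truths: competing-risk blocks followed by a final
    death-only block (the last line of therapy has no further transition)."""
    if n_blocks < 2:
        raise ValueError("a chained study needs at least 2 blocks")
    truths = [default_truth(n_patients=n_patients, n_events=2)]
    for _ in range(n_blocks - 2):
        truths.append(default_truth(n_patients=n_patients, n_events=2,
                                    include_prev_lot=True))
    truths.append(default_truth(n_patients=n_patients, n_events=1,
                                include_prev_lot=True))
    return truths
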