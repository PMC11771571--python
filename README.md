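# jmbiexp

Bayesian joint models of **nonlinear longitudinal biomarkers** and
**competing-risks outcomes**, with simultaneous (joint) estimation, a
corrected two-stage estimator, and individual dynamic prediction of
cumulative incidence.

## The problem

In multiple myeloma, serum paraprotein concentrations (M-spike from protein
electrophoresis, involved free light chains) fall under treatment and rise
again at relapse. Within one line of therapy (LoT), a patient faces two
competing clinical events — death, or transition to the next LoT — and the
shape of the biomarker trajectory carries prognostic information about both.
`jmbiexp` models each LoT as an independent block with its clock reset at the
block start:

* **Longitudinal submodel** — each biomarker follows a bi-exponential mixed
  model

  `y_ki(t) = B_ki (e^{G_ki t} + e^{-D_ki t} - 1) + ε, ε ~ N(0, σ_k²)`

  with subject-level baseline `B = exp(θ₁+b₁)`, growth rate `G = exp(θ₂+b₂)`
  and decay rate `D = exp(θ₃+b₃)`; random effects `b ~ N(0, Ω_k)`.
* **Survival submodel** — cause-specific Weibull proportional hazards

  `h_v(t) = φ_v t^{φ_v-1} exp(β₀_v + X'β_v + Σ_k α_kv·(B*_k, G*_k, D*_k))`

  sharing the *log-scale trajectory parameters* `B* = log B` etc. with the
  longitudinal submodel; `S(t) = exp(-H₁(t) - H₂(t))`.
* **Estimation** — `JointModel` samples everything at once (JE);
  `TwoStageModel` first fits each biomarker alone and plugs point estimates
  `(θ̂, Ω̂, σ̂)` into a second stage that samples the survival parameters
  *and re-estimates the random effects under the full joint likelihood* —
  the correction that removes the classic two-stage bias.
* **Dynamic prediction** — for a patient event-free at time `t`, the
  conditional cumulative incidence `F_v(u,t) = E[CIF_v(u,t)/S(t)]` is
  estimated by Monte Carlo over posterior draws and conditional
  random-effects draws given the patient's accumulated measurements.
* **Validation** — IPCW time-dependent AUC for competing risks, calibration
  against Aalen-Johansen observed risk, IWRES and Cox-Snell residuals.

A fully specified synthetic-data generator (`jmbiexp.simulate`) emulates the
structure of a first-line cohort — two biomarkers on irregular visit grids,
an event mix of roughly 15% death / 51% next-LoT / 34% censored over a
two-year window, covariates with missingness, and chained blocks with clock
reset — and exposes the latent truth for recovery experiments.

## Worked example

```python
import numpy as np
from dataclasses import replace
import jmbiexp as jm
from jmbiexp.data import preprocess_covariates
from jmbiexp.simulate import VisitSchedule

truth = replace(jm.default_truth(n_patients=250),
                visits=VisitSchedule(mean_gap=25.0))
block = jm.simulate_block(truth, seed=1)
cov, spec = preprocess_covariates(block.dataset.covariates,
                                  log_columns=("albumin",))
ds = jm.BlockDataset(1, block.dataset.series, block.dataset.outcomes,
                     cov, n_events=2)

model = jm.JointModel(chains=2, n_warmup=650, n_samples=1950, seed=11,
                      max_doublings=1).fit(ds)
print("converged:", model.converged_)
print("theta (M-spike):", np.round(model.posterior_.mean("theta")[0], 2))
print("truth          :", np.round(truth.biomarkers[0].theta, 2))
print("sigma:", np.round(model.posterior_.mean("sigma"), 2),
      "truth:", [b.sigma for b in truth.biomarkers])
print("phi  :", np.round(model.posterior_.mean("phi"), 2),
      "truth:", [e.phi for e in truth.events])
```

prints (a ~2-minute run on one CPU):

```
converged: True
theta (M-spike): [ 3.24 -6.5  -3.89]
truth          : [ 3.22 -6.5  -3.91]
sigma: [1.   0.35] truth: [1.0, 0.35]
phi  : [0.88 1.05] truth: [0.9, 1.1]
```

i.e., the population log baseline/growth/decay of the M-spike-like biomarker,
both residual SDs and both Weibull shapes are recovered within their
posterior uncertainty, and the run passed the convergence gates
(split-R-hat < 1.05, ESS > 100; `max_doublings=1` re-runs once with doubled
lengths if a gate fails). Dynamic predictions for a new patient then come
from `model.predict_cif(history, horizons=[455.0])` where `history` is a
`PatientHistory` with the patient's measurements up to the landmark.

The same workflow is scriptable from a shell:

```bash
jmbiexp simulate --n-patients 250 --seed 7 --out-dir data/
jmbiexp split    --longitudinal data/block_longitudinal.csv \
                 --survival data/block_survival.csv \
                 --covariates data/block_covariates.csv \
                 --fraction 0.8 --seed 7 --out-dir data/split/
jmbiexp fit      --longitudinal data/split/train_longitudinal.csv \
                 --survival data/split/train_survival.csv \
                 --covariates data/split/train_covariates.csv \
                 --mode two-stage --log-columns albumin \
                 --seed 7 --out-dir runs/ts/
```

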