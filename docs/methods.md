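# Methods

This note documents the model, the estimation machinery, the synthetic-data
generator and the numerical choices made where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model

One *block* is a line of therapy (LoT) with its own clock starting at the
first treatment day. Blocks are modelled independently (a blockwise scheme
rather than one multistate likelihood), which keeps each posterior tractable
and lets blocks run in parallel; the price is that cross-block dependence is
carried only through covariates (time spent in the previous LoT).

**Longitudinal.** Biomarker `k` of patient `i` follows
`μ_ki(t) = B_ki (e^{G_ki t} + e^{-D_ki t} - 1)` with additive iid Gaussian
error of SD `σ_k`. The subject parameters are positive by construction:
`(B, G, D) = exp(θ_k + b_ki)` with population means `θ_k ∈ R³` and random
effects `b_ki ~ N(0, Ω_k)`, `Ω_k` unstructured SPD. The curve declines,
reaches a nadir at `t* = ln(D/G)/(G+D)` when `D > G`, and regrows. The two
biomarkers are independent univariate submodels (no cross-biomarker
covariance); the module is generic in the number of biomarkers `K ≥ 1`.
Patients without measurements are legal: they contribute only survival
information, their random effects being identified by the prior and the
shared-parameter term.

**Survival.** Cause-specific Weibull proportional hazards for death (v=1)
and next-LoT (v=2):
`h_v(t) = φ_v t^{φ_v-1} exp(β₀_v + X'β_v + Σ_k α_kv·(B*, G*, D*)_k)` with
`B* = log B` etc. Because the shared terms are *time-constant log trajectory
parameters* (not the current biomarker value), the cumulative hazard is
closed-form, `H_v(t) = exp(β₀_v + η_v) t^{φ_v}`; quadrature is needed only
for cumulative incidence, `CIF_v(t,u) = ∫_t^u h_v S`, computed by
Gauss-Legendre with a configurable node count (default 30; tests use up to 60
where 1e-6 accuracy is asserted). The final LoT has a single hazard (death
only). Per-event covariate subsets are supported; the default uses the same
design for both events.

**Priors** (weakly informative): `N(0,10²)` on every unconstrained
coefficient (θ, β₀, β, α); half-Cauchy(0,5) on the residual scale σ (a
`sigma_prior_on="variance"` switch applies it literally to σ² instead, with
the Jacobian); half-Cauchy(0,1) on each Weibull shape φ;
inverse-Wishart(I₃, 4) on each Ω.

## Estimation

**Joint estimation (JE)** targets the full posterior of
`(θ_k, Ω_k, σ_k, b, φ_v, β₀_v, β_v, α_kv)`.

**Corrected two-stage (TS)**: stage 1 fits each biomarker's longitudinal
submodel alone and condenses it to plug-ins `(θ̂, Ω̂, σ̂)` — implemented as
the posterior mean of a longitudinal-only MCMC run (these posteriors are
unimodal at the sample sizes involved, so mode and mean coincide to within
Monte Carlo error). Stage 2 samples the survival parameters *and all random
effects* from the full joint likelihood with the plug-ins fixed; retaining
the longitudinal density in the random-effects conditional is the bias
correction. Setting `naive=True` drops that density, reproducing the classic
biased two-stage; it exists purely as an experimental foil. Stage 2 does not
re-estimate σ̂ (the plug-in set is held fixed as conditioned upon).

### The MCMC engine

No probabilistic-programming backend is used; the sampler is an adaptive
Metropolis-within-Gibbs scheme written for this model's specific geometry:

* **Random effects** are updated patient-parallel (they are conditionally
  independent): an Ω-shaped random walk with per-patient adaptive step
  sizes, a componentwise pass, and a *multi-basin independence proposal*.
  The latter matters: with additive error on trajectories that can span two
  orders of magnitude, a patient's likelihood in `b`-space is a razor-thin
  curved ridge, and monotone series leave the decay rate near-unidentified,
  producing genuinely multimodal per-patient posteriors. At initialization
  the sampler locates each patient's likelihood basins by multi-start
  coordinate descent, stores the local Gauss-Newton curvature of each basin,
  and proposes from the resulting fixed Gaussian mixture (anchored in
  absolute log-parameter space, converted with the current θ). The same
  curvature shapes the random-walk proposals.
* **Translation move**: `θ_k → θ_k + δ`, `b_k → b_k − δ` leaves every
  likelihood term invariant (they depend on θ+b only) and costs two prior
  evaluations; it removes the dominant posterior ridge between population
  means and random effects.
* **θ_k and each event's survival vector** `(log φ, β₀, β, α)` use
  Haario-style covariance-adapted multivariate random walks (plus a
  componentwise scan early in warmup). The survival block is sampled in a
  *centered parameterization*: β₀ internally absorbs `x̄'β + Σ_k α_k·c_k +
  φ·mean(log T)` (c_k = coarse trajectory medians), which decorrelates the
  intercept from slopes and shapes; draws are recorded on the natural scale.
* **Laplace independence proposals for the survival block**: given the
  random effects, the survival log-posterior is concave in
  `(β₀, β, α, φ)` jointly (the cumulative-hazard term is `-exp` of a linear
  form; the event terms are linear plus `log φ`), so a Newton fit of the
  conditional mode and curvature yields a near-exact Gaussian proposal each
  sweep (warm-started across sweeps). Drawn mostly as an antithetic
  overrelaxation through the conditional mode, with plain independence
  draws mixed in. This is what lets weakly identified association
  coefficients — whose marginal posterior approaches the prior — traverse
  their full range. All likelihood bookkeeping is incremental: per-event
  linear predictors and log-likelihood vectors are cached and only the
  moved component is recomputed (verified against full recomputation to
  1e-14 in development).
* **Ω_k** is conjugate given `b`: exact inverse-Wishart Gibbs draws.
* **log σ_k**: scalar adaptive random walk.
* **Warmup-only basin polish**: at four points of warmup each patient's `b`
  is greedily reassigned to the best of the current value, the coarse fit,
  zero, prior draws and coordinate-grid perturbations. This runs only before
  the sampling phase (so detailed balance is untouched) and removes the slow
  one-patient-at-a-time drift that local kernels exhibit.

All adaptation stops at the end of warmup. Initialization: θ from medians of
crude per-patient curve fits, `b` from the per-patient residuals of those
fits, φ = 1, α = β = 0, β₀ from the crude event rate, with per-chain jitter.
Convergence is gated at split-R-hat < 1.05 and bulk ESS > 100 (arviz), over
at least two chains; a failed gate is a *flagged result*, never an
exception, and `fit_joint` can optionally re-run with doubled lengths until
the gates pass (run length as the minimum achieving convergence).

Determinism: a single root seed drives chain seeds through
`numpy.random.SeedSequence`; identical configuration reproduces draws
bit-for-bit.

Default run lengths follow the reference analysis pattern: three chains,
1000 warmup and ≈4000 pooled draws for JE and TS stage 1; 500 warmup and
≈1000 pooled draws for TS stage 2.

## Dynamic prediction

For a patient event-free at landmark `t` with history `y*(≤t)` and design
`X`, per retained posterior draw `j`: draw
`b ~ π(b | T > t, y*, Θ^(j))` — the target includes the survival factor
`S(t|b)` — with a short adaptive random-walk Metropolis chain
(default 50 adaptation + 50 kept iterations, warm-started at the previous
draw's state), then evaluate `F_v^(j)(u,t) = CIF_v(t,u)/S(t)` in closed form
plus quadrature. Point estimate = mean over draws; bands = 2.5/97.5
Monte Carlo percentiles. `J` defaults to all retained draws, subsampled
without replacement when fewer are requested. The TS variant fixes
`(θ̂, Ω̂, σ̂)` at the plug-ins and resamples only the survival parameters
across draws. Landmark times are on the block clock.

## Validation metrics

* **IPCW time-dependent AUC** (cumulative cases / dynamic controls): cases
  experience the indexed event in `(t, t+Δ]`; event-free-beyond-horizon and
  competing-event-by-horizon patients are controls; censored-in-window
  patients drop out, compensated by Kaplan-Meier censoring weights estimated
  on the at-risk set at the landmark (cases and competing-event controls
  weighted by `1/G(T⁻)`, event-free controls by `1/G(Δ)`); prediction ties
  count ½. With no censoring the estimator reduces *exactly* to the
  empirical AUC.
* **Calibration**: quantile groups of predicted risk versus the
  Aalen-Johansen cumulative incidence within each group (1−KM would
  overstate cause-specific risk under competing events); grouping fails
  loudly when groups would hold fewer than two patients.
* **Residuals**: IWRES `(y−ŷ)/σ̂` (standard normal under a correct
  longitudinal model) and Cox-Snell `H₁(T)+H₂(T)` (unit exponential under a
  correct survival model, compared by Kaplan-Meier against `e^{-x}`).

## Synthetic-data generator

The generator is the package's study design, not a test fixture. Defaults
emulate a first-line myeloma cohort:

| quantity | default | rationale |
|---|---|---|
| biomarker 1 (M-spike-like) | θ = log(25, 0.0015, 0.02), σ = 1.0 g/L | decline from ~25 g/L to a nadir near day 140, slow regrowth |
| biomarker 2 (FLC-like) | θ = log(4, 0.002, 0.015), σ = 0.35 g/L | same shape at lower concentration |
| random effects | Ω = diag(0.16, 0.25, 0.25) + 0.01 off-diagonal | ~±50% subject spread in rates |
| covariates | age (65±10), albumin (lognormal, 15% missing), ECOG 2+ (30%, 5% missing) | mixed types with missingness |
| hazards | φ = (0.9, 1.1); β, α moderate; β₀ calibrated | see below |
| visits | first at day 0, gamma gaps, mean 30 d | irregular schedules |
| censoring | administrative at 730 d + exponential rate 0.0012/d | ~⅓ censored |

The Weibull log-scales β₀ are calibrated analytically so the average
subject's cause-specific cumulative hazards at a 230-day reference match
target rates of 0.00068/d (death) and 0.0023/d (transition), including a
lognormal mean correction `exp(E η + Var η/2)` for the spread of the linear
predictor. One large simulation (n = 20 000) verifies the resulting mix:
15.1% death / 52.3% next-LoT / 32.6% censored, with median block times of
140-190 days — the intended first-line-like structure. These are
calibration targets of the generator, not claims about any external cohort.

Latent cause-specific times are drawn by inverting each cause's cumulative
hazard with independent uniforms; independence of the latent times is a
simulation device (the cause-specific hazards fully determine the
observed-data likelihood). Chained studies pass the δ=2 patients of block
`l` into block `l+1` with fresh random effects and the observed block-`l`
time as a covariate (log-standardized inside the generator); the final block
is death-only.

What the generator does *not* emulate: informative (MNAR) dropout, visit
schedules that react to disease state, treatment-regimen effects,
measurement error that scales with concentration, and cross-biomarker
correlation. Passing recovery tests therefore demonstrate correctness of
the machinery under the stated generative model, not robustness to these
real-data features.

## Problem sizes used by the test suite and acceptance script

The replicated recovery/equivalence study runs 20 replicates (tests; the
acceptance script runs 5) of n = 250 patients with ~8 visits per patient
(mean visit gap 25 days), fitted with 2 chains, 650 warmup + 1950 kept
draws for JE, 300+600 for TS stage 1, and 250+500 for stage 2. Run lengths
are chosen so the convergence gates pass for most replicates with this
sampler; replicates that miss a gate stay in the study with their verdict
attached (the coverage assertions are about the posterior, which remains
valid to Monte Carlo accuracy at these effective sample sizes). The
generator-correctness checks run at n = 100 000; metric checks at
n = 300-1000.

## Known limitations

* Per-patient multimodality is handled by basin search plus independence
  mixtures; pathological series (very long monotone growth far beyond the
  calibrated horizon) can still mix slowly, which the convergence gates
  flag honestly.
* In replicated recovery experiments the marginal credible intervals of the
  most weakly identified association coefficients (the decay-rate
  associations, whose identification rests on modest between-patient
  variation in `D*`) can be mildly anti-conservative: the replicate-level
  spread of their posterior means slightly exceeds the claimed posterior SD.
  The generator's covariate missingness (mean-imputed at fit time while the
  generative hazard used the true values) contributes a deliberate,
  realistic misspecification here.
* Stage-1 plug-ins are posterior means; a Laplace-marginalized optimizer is
  a possible alternative reading of the two-stage construction and was not
  implemented.
* The IPCW AUC uses one specific estimator variant (documented above);
  other variants differ in their treatment of competing-event subjects.
* Blocks are independent by design; no information is shared across LoTs
  beyond carried covariates.
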