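"""Posterior density, priors, convergence gating, stage-1/stage-2 contracts."""

import numpy as np
import pytest
from scipy import stats as sps

import jmbiexp as jm
from jmbiexp.inference import convergence_report, fit_stage1
from jmbiexp.mcmc import (CompiledBlock, JointState, PosteriorSamples,
                          SurvParams, compute_diagnostics,
                          log_joint_posterior)
from jmbiexp.priors import PriorConfig


def random_state(cb, rng, scale=0.3):
    theta = np.stack([np.array([3.0, -6.3, -4.0]) + rng.normal(scale=0.2, size=3)
                      for _ in range(cb.K)])
    return JointState(
        theta=theta,
        log_sigma=rng.normal(scale=0.2, size=cb.K),
        omega=np.stack([0.2 * np.eye(3) + 0.02 * np.ones((3, 3))] * cb.K),
        b=rng.normal(scale=scale, size=(cb.K, cb.n, 3)),
        surv=[SurvParams(log_phi=float(rng.normal(scale=0.1)),
                         beta0=float(rng.normal(-6.5, 0.5)),
                         beta=rng.normal(scale=0.2, size=cb.p[v]),
                         alpha=rng.normal(scale=0.1, size=(cb.K, 3)))
              for v in range(cb.n_events)],
    )


def oracle_log_posterior(dataset, state, priors, biomarkers=None):
    """From-scratch per-patient summation using the public per-subject
    operations — independent of the vectorized sampler path."""
    total = 0.0
    patients = dataset.patient_ids
    bios = biomarkers if biomarkers is not None else dataset.biomarker_ids
    X = dataset.covariates.design_matrix()
    rows = {p: i for i, p in enumerate(dataset.covariates.patient_ids)}
    for k_idx, k in enumerate(bios):
        pop = jm.BiExpPopulation(state.theta[k_idx],
                                 state.omega[k_idx],
                                 float(np.exp(state.log_sigma[k_idx])))
        for i, pid in enumerate(patients):
            subj = jm.BiExpSubject(state.b[k_idx, i])
            total += jm.longitudinal_loglik(dataset.get_series(pid, k), pop, subj)
            total += float(sps.multivariate_normal.logpdf(
                state.b[k_idx, i], mean=np.zeros(3), cov=state.omega[k_idx]))
        total += float(np.sum(sps.norm.logpdf(state.theta[k_idx], 0, priors.coef_sd)))
        total += float(sps.halfcauchy.logpdf(np.exp(state.log_sigma[k_idx]),
                                             scale=priors.sigma_scale))
        total += float(sps.invwishart.logpdf(state.omega[k_idx],
                                             df=priors.wishart_df,
                                             scale=priors.wishart_scale))
    model = jm.CompetingRisksModel(tuple(
        jm.HazardSpec(float(np.exp(s.log_phi)), s.beta0, s.beta, s.alpha)
        for s in state.surv))
    for i, (pid, outcome) in enumerate(zip(patients, dataset.outcomes)):
        logs = state.theta + state.b[:, i, :]
        total += jm.survival_loglik(model, outcome, X[rows[pid]], logs)
    for s in state.surv:
        coefs = np.concatenate([[s.beta0], s.beta, s.alpha.ravel()])
        total += float(np.sum(sps.norm.logpdf(coefs, 0, priors.coef_sd)))
        total += float(sps.halfcauchy.logpdf(np.exp(s.log_phi),
                                             scale=priors.phi_scale))
    return total


class TestLogJointPosterior:
    def test_matches_per_patient_oracle(self, small_block):
        _, ds = small_block
        cb = CompiledBlock(ds)
        priors = PriorConfig()
        rng = np.random.default_rng(17)
        for _ in range(5):
            state = random_state(cb, rng)
            got = log_joint_posterior(ds, state, priors, compiled=cb)
            want = oracle_log_posterior(ds, state, priors)
            assert got == pytest.approx(want, abs=1e-8)

    def test_removing_patient_changes_by_their_contribution(self, small_block):
        _, ds = small_block
        cb = CompiledBlock(ds)
        rng = np.random.default_rng(3)
        state = random_state(cb, rng)
        full = log_joint_posterior(ds, state, compiled=cb)

        drop = ds.patient_ids[5]
        reduced = ds.subset([p for p in ds.patient_ids if p != drop])
        cb_red = CompiledBlock(reduced)
        keep = [i for i, p in enumerate(ds.patient_ids) if p != drop]
        state_red = JointState(state.theta, state.log_sigma, state.omega,
                               state.b[:, keep, :], state.surv)
        partial = log_joint_posterior(reduced, state_red, compiled=cb_red)
        # the dropped patient's contribution, computed independently
        contrib = oracle_log_posterior(
            ds.subset([drop]),
            JointState(state.theta, state.log_sigma, state.omega,
                       state.b[:, [5], :], state.surv),
            PriorConfig(), biomarkers=ds.biomarker_ids)
        priors_only = oracle_log_posterior(
            ds.subset([]),
            JointState(state.theta, state.log_sigma, state.omega,
                       state.b[:, :0, :], state.surv), PriorConfig(),
            biomarkers=ds.biomarker_ids)
        assert full - partial == pytest.approx(contrib - priors_only, abs=1e-7)

    def test_prior_scale_changes_only_prior_term(self, small_block):
        _, ds = small_block
        cb = CompiledBlock(ds)
        rng = np.random.default_rng(4)
        state = random_state(cb, rng)
        a = log_joint_posterior(ds, state, PriorConfig(sigma_scale=5.0), compiled=cb)
        b = log_joint_posterior(ds, state, PriorConfig(sigma_scale=10.0), compiled=cb)
        sig = float(np.exp(state.log_sigma[0]))
        sigs = np.exp(state.log_sigma)
        want = float(sum(sps.halfcauchy.logpdf(s, scale=10.0)
                         - sps.halfcauchy.logpdf(s, scale=5.0) for s in sigs))
        assert b - a == pytest.approx(want, abs=1e-10)


class TestPriorConfig:
    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            PriorConfig(coef_sd=-1.0)
        with pytest.raises(ValueError):
            PriorConfig(wishart_df=2.0)  # must exceed dim - 1 = 2... 3x3 needs > 2
        with pytest.raises(ValueError):
            PriorConfig(sigma_prior_on="mean")

    def test_variance_placement_includes_jacobian(self):
        scale_prior = PriorConfig(sigma_prior_on="scale")
        var_prior = PriorConfig(sigma_prior_on="variance")
        s = 1.7
        want = float(sps.halfcauchy.logpdf(s ** 2, scale=5.0)) + np.log(2 * s)
        assert var_prior.logp_sigma(s) == pytest.approx(want, abs=1e-12)
        assert scale_prior.logp_sigma(s) == pytest.approx(
            float(sps.halfcauchy.logpdf(s, scale=5.0)), abs=1e-12)


class TestConvergenceReport:
    def test_identical_chains_rhat_one(self):
        draws = np.random.default_rng(0).standard_normal((1, 400, 2))
        copies = {"x": np.repeat(draws, 2, axis=0)}
        diag = compute_diagnostics(copies)
        assert np.all(diag["rhat"] <= 1.001)

    def test_independent_normal_chains_pass(self):
        rng = np.random.default_rng(1)
        diag = compute_diagnostics({"x": rng.standard_normal((3, 1000, 2))})
        assert bool(diag["pass"].all())

    def test_shifted_chain_fails(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((2, 500))
        arr[1] += 10.0
        diag = compute_diagnostics({"x": arr[:, :, None]})
        assert diag["rhat"].iloc[0] > 1.5
        assert not diag["pass"].iloc[0]

    def test_single_chain_rejected(self):
        samples = PosteriorSamples(
            draws={"x": np.zeros((1, 10, 1))})
        with pytest.raises(ValueError, match="2 chains"):
            convergence_report(samples)


class TestStage1Contracts:
    def test_degenerate_all_empty_rejected(self):
        series = [jm.BiomarkerSeries(f"P{i}", 1, [], []) for i in range(4)]
        with pytest.raises(ValueError, match="empty"):
            fit_stage1(series)

    def test_biomarker_order_irrelevant(self, small_block):
        _, ds = small_block
        sub = ds.subset(ds.patient_ids[:30])
        p1 = fit_stage1(sub, biomarker_id=1, chains=2, n_warmup=150,
                        n_samples=150, seed=5)
        p2 = fit_stage1(sub, biomarker_id=2, chains=2, n_warmup=150,
                        n_samples=150, seed=6)
        p1_again = fit_stage1(sub, biomarker_id=1, chains=2, n_warmup=150,
                              n_samples=150, seed=5)
        np.testing.assert_array_equal(p1.theta, p1_again.theta)
        assert not np.allclose(p1.theta, p2.theta)
        assert p1.sigma[0] > 0
        assert np.all(np.linalg.eigvalsh(p1.omega[0]) > 0)


class TestDeterminism:
    def test_identical_seeds_identical_draws(self, small_block):
        _, ds = small_block
        sub = ds.subset(ds.patient_ids[:25])
        a = jm.fit_joint(sub, chains=2, n_warmup=100, n_samples=100, seed=9)
        b = jm.fit_joint(sub, chains=2, n_warmup=100, n_samples=100, seed=9)
        for key in a.draws:
            np.testing.assert_array_equal(a.draws[key], b.draws[key])
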