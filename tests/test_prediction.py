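"""Dynamic conditional prediction: conditional random-effects draws,
CIF estimates, trajectory updates, and the two-stage variant."""

import numpy as np
import pytest

import jmbiexp as jm
from jmbiexp.data import BiomarkerSeries
from jmbiexp.mcmc import PosteriorSamples, SurvParams
from jmbiexp.prediction import (DrawState, PatientHistory,
                                draw_conditional_random_effects, predict_cif,
                                predict_cif_ts, predict_trajectory)

OMEGA = 0.25 * np.eye(3)


def degenerate_samples(rate1=0.1, rate2=0.2, n_draws=40):
    """Posterior concentrated on two constant hazards with no associations."""
    draws = {
        "theta": np.tile(np.array([2.0, -6.0, -4.0]), (1, n_draws, 1, 1)),
        "omega": np.tile(OMEGA, (1, n_draws, 1, 1, 1)),
        "sigma": np.full((1, n_draws, 1), 0.5),
        "phi": np.ones((1, n_draws, 2)),
        "beta0": np.tile(np.log([rate1, rate2]), (1, n_draws, 1)),
        "alpha1": np.zeros((1, n_draws, 1, 3)),
        "alpha2": np.zeros((1, n_draws, 1, 3)),
    }
    return PosteriorSamples(draws=draws)


def empty_history(landmark=0.0):
    return PatientHistory(
        (BiomarkerSeries("p", 1, [], []),), np.zeros(0), landmark)


class TestConditionalDraws:
    def test_prior_limit_for_empty_history(self):
        """With no measurements and landmark 0 the conditional is the prior."""
        from scipy import stats as sps
        state = DrawState(theta=np.array([[2.0, -6.0, -4.0]]),
                          omega=OMEGA[None], sigma=np.array([0.5]), surv=())
        rng = np.random.default_rng(0)
        hist = empty_history()
        draws = []
        b = None
        for _ in range(1200):
            b, _sc = draw_conditional_random_effects(
                hist, state, rng, n_adapt=10, n_iter=10, init=b)
            draws.append(b[0].copy())
        draws = np.asarray(draws)[::3]
        for c in range(3):
            ks = sps.kstest(draws[:, c], "norm", args=(0.0, 0.5))
            assert ks.pvalue > 1e-3

    def test_informative_history_shrinks_posterior(self):
        rng = np.random.default_rng(1)
        theta = np.array([[3.0, -6.3, -4.0]])
        b_true = np.array([[0.3, -0.2, 0.1]])
        B, G, D = np.exp(theta[0] + b_true[0])
        times = np.linspace(0.0, 400.0, 30)
        y = jm.biexp_mean(B, G, D, times) + 0.05 * rng.standard_normal(30)
        state = DrawState(theta=theta, omega=OMEGA[None],
                          sigma=np.array([0.05]), surv=())
        hist = PatientHistory((BiomarkerSeries("p", 1, times, y),),
                              np.zeros(0), 400.0)
        draws, b = [], None
        for _ in range(400):
            b, _sc = draw_conditional_random_effects(
                hist, state, rng, n_adapt=15, n_iter=15, init=b)
            draws.append(b[0].copy())
        draws = np.asarray(draws)
        # posterior SD of the baseline effect shrinks at least 5x vs the prior
        assert draws[:, 0].std() < 0.5 / 5.0
        assert abs(draws[:, 0].mean() - b_true[0, 0]) < 0.1

    def test_zero_association_matches_longitudinal_only_conditional(self):
        surv = (SurvParams(0.0, -6.0, np.zeros(0), np.zeros((1, 3))),)
        state = DrawState(theta=np.array([[2.0, -6.0, -4.0]]),
                          omega=OMEGA[None], sigma=np.array([0.5]), surv=surv)
        times = np.array([0.0, 50.0, 120.0])
        y = np.array([7.0, 6.0, 5.5])
        hist = PatientHistory((BiomarkerSeries("p", 1, times, y),),
                              np.zeros(0), 150.0)
        b1, _ = draw_conditional_random_effects(
            hist, state, np.random.default_rng(7), include_survival=True)
        b2, _ = draw_conditional_random_effects(
            hist, state, np.random.default_rng(7), include_survival=False)
        # alpha = 0 makes the survival factor constant in b: identical chains
        np.testing.assert_array_equal(b1, b2)


class TestPredictCif:
    def test_zero_horizon_gives_zero(self):
        pred = predict_cif(empty_history(), degenerate_samples(),
                           horizons=[0.0], J=10, seed=0)
        np.testing.assert_array_equal(pred.mean, 0.0)

    def test_constant_hazard_closed_form(self):
        pred = predict_cif(empty_history(), degenerate_samples(),
                           horizons=[1.0], J=20, seed=0,
                           quadrature_nodes=40)
        want = (0.1 / 0.3) * (1 - np.exp(-0.3))
        assert pred.mean[0, 0] == pytest.approx(want, abs=1e-8)
        assert pred.mean[1, 0] == pytest.approx(2 * want, abs=1e-8)
        # degenerate posterior, no association: zero-width bands
        np.testing.assert_allclose(pred.upper - pred.lower, 0.0, atol=1e-12)

    def test_per_draw_conditional_identity(self, small_block, joint_fit):
        blk, ds = small_block
        hist = _history_from_block(blk, ds, landmark=120.0)
        horizons = np.array([180.0, 365.0, 540.0])
        pred = predict_cif(hist, joint_fit, horizons, J=40, seed=3,
                           quadrature_nodes=60)
        total = pred.per_draw.sum(axis=1) + pred.survival_ratio
        np.testing.assert_allclose(total, 1.0, atol=1e-6)

    def test_monotone_in_horizon_and_bands_ordered(self, small_block, joint_fit):
        blk, ds = small_block
        hist = _history_from_block(blk, ds, landmark=120.0)
        horizons = np.linspace(130.0, 700.0, 12)
        pred = predict_cif(hist, joint_fit, horizons, J=40, seed=4)
        for v in range(2):
            assert np.all(np.diff(pred.mean[v]) >= -1e-10)
            assert np.all(np.diff(pred.per_draw[:, v, :], axis=1) >= -1e-10)
        assert np.all(pred.lower <= pred.mean + 1e-12)
        assert np.all(pred.mean <= pred.upper + 1e-12)
        assert np.all(pred.per_draw.sum(axis=1) <= 1.0 + 1e-9)

    def test_bit_reproducible(self, small_block, joint_fit):
        blk, ds = small_block
        hist = _history_from_block(blk, ds, landmark=100.0)
        a = predict_cif(hist, joint_fit, [400.0], J=25, seed=11)
        b = predict_cif(hist, joint_fit, [400.0], J=25, seed=11)
        np.testing.assert_array_equal(a.per_draw, b.per_draw)

    def test_horizon_before_landmark_rejected(self, small_block, joint_fit):
        blk, ds = small_block
        hist = _history_from_block(blk, ds, landmark=100.0)
        with pytest.raises(ValueError):
            predict_cif(hist, joint_fit, [50.0], J=5, seed=0)

    def test_landmark_consistency(self, small_block, joint_fit):
        """Predicting at t then conditioning on survival to t' agrees with
        predicting directly at t' (no new data in between)."""
        blk, ds = small_block
        t, t2, u = 100.0, 200.0, 500.0
        hist_t = _history_from_block(blk, ds, landmark=t)
        hist_t2 = PatientHistory(hist_t.series, hist_t.X, t2)
        pred_t = predict_cif(hist_t, joint_fit, [t2, u], J=400, seed=5)
        pred_t2 = predict_cif(hist_t2, joint_fit, [u], J=400, seed=6)
        s_ratio = pred_t.survival_ratio[:, 0]       # S(t2)/S(t) per draw
        for v in range(2):
            num = pred_t.per_draw[:, v, 1] - pred_t.per_draw[:, v, 0]
            derived = num.mean() / s_ratio.mean()
            direct = pred_t2.mean[v, 0]
            mc_se = np.sqrt(num.var() / num.size) / s_ratio.mean() \
                + np.sqrt(pred_t2.per_draw[:, v, 0].var() / 400)
            assert abs(derived - direct) < max(4 * mc_se, 0.02)


def _history_from_block(blk, ds, landmark):
    """First simulated patient still at risk at the landmark."""
    for i, outcome in enumerate(ds.outcomes):
        if outcome.time > landmark:
            pid = outcome.patient_id
            series = []
            for k in ds.biomarker_ids:
                s = ds.get_series(pid, k)
                keep = s.times <= landmark
                series.append(BiomarkerSeries(pid, k, s.times[keep],
                                              s.values[keep]))
            X = ds.covariates.design_matrix()[
                list(ds.covariates.patient_ids).index(pid)]
            return PatientHistory(tuple(series), X, landmark)
    raise AssertionError("no patient at risk at the landmark")


class TestTrajectory:
    def test_degenerate_posterior_reproduces_curve(self):
        samples = degenerate_samples()
        hist = empty_history()
        grid = np.linspace(0.0, 300.0, 7)
        # concentrate random effects by shrinking omega to near zero
        samples.draws["omega"] = np.tile(1e-12 * np.eye(3),
                                         (1, samples.n_draws, 1, 1, 1))
        out = predict_trajectory(hist, samples, grid, J=10, seed=0)
        curve = out[1]
        B, G, D = np.exp([2.0, -6.0, -4.0])
        np.testing.assert_allclose(curve[1], jm.biexp_mean(B, G, D, grid),
                                   rtol=1e-3)
        assert np.all(curve[3] - curve[2] < 1e-3)

    def test_band_covers_truth_mostly(self, small_block, joint_fit):
        blk, ds = small_block
        truth = blk.truth
        grid = np.linspace(0.0, 300.0, 10)
        hits = total = 0
        for i, outcome in enumerate(ds.outcomes[:6]):
            if outcome.time <= 150.0:
                continue
            hist = _history_from_block_patient(blk, ds, i, landmark=150.0)
            out = predict_trajectory(hist, joint_fit, grid, J=120,
                                     seed=20 + i)
            for k_idx, k in enumerate(ds.biomarker_ids):
                B, G, D = np.exp(truth.biomarkers[k_idx].theta
                                 + blk.b[k_idx, i])
                mu = np.asarray(jm.biexp_mean(B, G, D, grid))
                curve = out[k]
                hits += int(np.sum((curve[2] <= mu) & (mu <= curve[3])))
                total += grid.size
        assert total > 0
        assert hits / total >= 0.8


def _history_from_block_patient(blk, ds, i, landmark):
    pid = ds.patient_ids[i]
    series = []
    for k in ds.biomarker_ids:
        s = ds.get_series(pid, k)
        keep = s.times <= landmark
        series.append(BiomarkerSeries(pid, k, s.times[keep], s.values[keep]))
    X = ds.covariates.design_matrix()[
        list(ds.covariates.patient_ids).index(pid)]
    return PatientHistory(tuple(series), X, landmark)


class TestTwoStageVariant:
    def test_degenerate_ts_matches_je(self):
        samples = degenerate_samples()
        plugins = jm.PluginEstimates(
            theta=np.array([[2.0, -6.0, -4.0]]),
            omega=OMEGA[None], sigma=np.array([0.5]))
        hist = empty_history()
        je = predict_cif(hist, samples, [1.0], J=15, seed=2)
        ts = predict_cif_ts(hist, samples, plugins, [1.0], J=15, seed=2)
        np.testing.assert_allclose(je.mean, ts.mean, atol=1e-10)

    def test_ts_bit_reproducible(self):
        samples = degenerate_samples()
        plugins = jm.PluginEstimates(
            theta=np.array([[2.0, -6.0, -4.0]]),
            omega=OMEGA[None], sigma=np.array([0.5]))
        hist = empty_history()
        a = predict_cif_ts(hist, samples, plugins, [1.0, 2.0], J=12, seed=9)
        b = predict_cif_ts(hist, samples, plugins, [1.0, 2.0], J=12, seed=9)
        np.testing.assert_array_equal(a.per_draw, b.per_draw)
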