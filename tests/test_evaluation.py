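"""Metric correctness: exhaustive-pair c-index oracle, hand-computed IPCW
Brier scores, calibration slope consistency, and bootstrap optimism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sksurv.metrics import brier_score as sksurv_brier
from sksurv.util import Surv

from survscreen import coxcore, evaluation
from survscreen.simdata import (ScenarioConfig, SurvivalOutcome, gen_dataset)

from conftest import make_censored


def c_index_oracle(lp, outcome):
    """Exhaustive pair enumeration with the package's tie conventions."""
    t, d = outcome.time, outcome.event
    conc = comp = 0.0
    for i in range(t.size):
        for j in range(t.size):
            if d[i] == 1 and t[i] < t[j]:
                comp += 1
                if lp[i] > lp[j]:
                    conc += 1
                elif lp[i] == lp[j]:
                    conc += 0.5
    return conc / comp


class TestHarrellC:
    def test_four_subject_hand_count(self):
        out = SurvivalOutcome(time=np.array([1.0, 2.0, 3.0, 4.0]),
                              event=np.ones(4, dtype=int))
        c = evaluation.harrell_c(np.array([4.0, 3.0, 1.0, 2.0]), out)
        assert c == pytest.approx(5 / 6)

    def test_perfect_ordering_gives_one(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(size=50) + 0.01
        out = SurvivalOutcome(time=t, event=np.ones(50, dtype=int))
        assert evaluation.harrell_c(-t, out) == 1.0

    def test_random_predictor_near_half(self):
        rng = np.random.default_rng(1)
        _, out = make_censored(rng, 2000)
        lp = rng.standard_normal(2000)
        # c-index SE for random predictions is below (n_pairs)^-1/2 scale;
        # 0.02 is > 3 SE at n=2000
        assert abs(evaluation.harrell_c(lp, out) - 0.5) < 0.02

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_pair_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        x, out = make_censored(rng, n, beta=0.5)
        lp = np.round(x, 1)  # induce predictor ties
        if out.event.sum() == 0 or not (out.time[out.event == 1].min()
                                        < out.time.max()):
            return
        assert evaluation.harrell_c(lp, out) == pytest.approx(
            c_index_oracle(lp, out))

    def test_tied_event_times_not_comparable(self):
        out = SurvivalOutcome(time=np.array([1.0, 1.0, 2.0]),
                              event=np.array([1, 1, 1]))
        # only pairs (1,3) and (2,3) comparable; both concordant
        c = evaluation.harrell_c(np.array([3.0, 1.0, 2.0]), out)
        assert c == pytest.approx(0.5)  # (1 + 0) / 2

    def test_no_comparable_pairs_raises(self):
        out = SurvivalOutcome(time=np.array([2.0, 1.0]),
                              event=np.array([1, 0]))
        with pytest.raises(ValueError):
            evaluation.harrell_c(np.array([1.0, 2.0]), out)


class TestBrierR2:
    def test_null_predictions_give_zero(self):
        rng = np.random.default_rng(2)
        _, out = make_censored(rng, 200)
        t_star = float(np.median(out.time))
        null_pred = np.full(200, evaluation.km_survival(out.time, out.event,
                                                        t_star)[0])
        assert evaluation.brier_r2(null_pred, out, t_star) == pytest.approx(0.0)

    def test_perfect_predictions_give_one(self):
        t = np.array([0.5, 0.8, 1.2, 3.0, 4.0, 5.0])
        out = SurvivalOutcome(time=t, event=np.ones(6, dtype=int))
        pred = (t > 2.0).astype(float)
        assert evaluation.brier_r2(pred, out, 2.0) == pytest.approx(1.0)

    def test_hand_computed_small_dataset(self):
        # n=10, one censored before t*: enumerate the IPCW Brier ratio
        time = np.array([0.5, 0.9, 1.1, 1.4, 1.8, 2.5, 3.0, 3.5, 4.0, 1.2])
        event = np.array([1, 1, 1, 1, 1, 1, 1, 1, 1, 0])
        out = SurvivalOutcome(time=time, event=event)
        pred = np.linspace(0.05, 0.95, 10)
        t_star = 2.0
        # censoring KM: single censoring at t=1.2 among 10 at risk after ...
        # G(t) drops to (1 - 1/7) at t=1.2 (7 at risk: times >= 1.2)
        G = lambda t: 1.0 if t < 1.2 else 6 / 7
        n = 10
        bs = 0.0
        for i in range(n):
            if time[i] <= t_star and event[i] == 1:
                bs += (0 - pred[i]) ** 2 / G(time[i] - 1e-12)
            elif time[i] > t_star:
                bs += (1 - pred[i]) ** 2 / G(t_star)
        bs /= n
        km2 = evaluation.km_survival(time, event, t_star)[0]
        bs_null = 0.0
        for i in range(n):
            if time[i] <= t_star and event[i] == 1:
                bs_null += (0 - km2) ** 2 / G(time[i] - 1e-12)
            elif time[i] > t_star:
                bs_null += (1 - km2) ** 2 / G(t_star)
        bs_null /= n
        expected = 1 - bs / bs_null
        assert evaluation.brier_r2(pred, out, t_star) == pytest.approx(
            expected, abs=1e-12)

    def test_matches_sksurv_brier_on_continuous_data(self):
        rng = np.random.default_rng(3)
        x, out = make_censored(rng, 300, beta=0.8)
        t_star = float(np.quantile(out.time, 0.4))
        fit = coxcore.fit_marginal(x, out)
        pred = evaluation.predict_survival(
            coxcore.CoxFit(beta=np.array([fit.beta_hat]), logpl=fit.utility,
                           information=np.array([[fit.information]]),
                           converged=True),
            x[:, None], out, x[:, None], t_star)
        y = Surv.from_arrays(event=out.event.astype(bool), time=out.time)
        _, bs_ref = sksurv_brier(y, y, pred, t_star)
        ours = evaluation._ipcw_brier(pred, out.time, out.event, t_star)
        assert ours == pytest.approx(bs_ref[0], abs=1e-10)

    def test_noise_strictly_degrades(self):
        t = np.linspace(0.2, 4.0, 40)
        out = SurvivalOutcome(time=t, event=np.ones(40, dtype=int))
        perfect = (t > 2.0).astype(float)
        rng = np.random.default_rng(4)
        noisy = np.clip(perfect + rng.uniform(-0.3, 0.3, 40), 0, 1)
        r_perfect = evaluation.brier_r2(perfect, out, 2.0)
        r_noisy = evaluation.brier_r2(noisy, out, 2.0)
        assert r_perfect == 1.0
        assert r_noisy < r_perfect

    def test_out_of_range_predictions_rejected(self):
        rng = np.random.default_rng(5)
        _, out = make_censored(rng, 20)
        with pytest.raises(ValueError):
            evaluation.brier_r2(np.full(20, 1.5), out, 1.0)


class TestCalibrationSlope:
    def test_true_model_slope_near_one(self):
        cfg = ScenarioConfig(n=4000, p=6, signal="strong", seed=21)
        sim = gen_dataset(cfg)
        pi = cfg.tau * sim.model.linear_predictor(sim.X.values)
        slope = evaluation.calibration_slope(pi, sim.outcome)
        # asymptotic SE of the slope is O(n^-1/2); 0.1 covers 3 SE here
        assert abs(slope - 1.0) < 0.1

    def test_scale_equivariance(self):
        rng = np.random.default_rng(6)
        x, out = make_censored(rng, 500, beta=1.0)
        s1 = evaluation.calibration_slope(x, out)
        s2 = evaluation.calibration_slope(2 * x, out)
        assert s2 == pytest.approx(s1 / 2, rel=1e-6)

    def test_noise_index_slope_near_zero(self):
        rng = np.random.default_rng(7)
        _, out = make_censored(rng, 3000)
        pi = rng.standard_normal(3000)
        fit = coxcore.fit_marginal(pi, out)
        assert abs(fit.beta_hat) < 3 / np.sqrt(fit.information)

    def test_large_sample_bias_below_two_percent(self):
        cfg = ScenarioConfig(n=10_000, p=6, signal="weak", seed=22)
        sim = gen_dataset(cfg)
        pi = cfg.tau * sim.model.linear_predictor(sim.X.values)
        assert abs(evaluation.calibration_slope(pi, sim.outcome) - 1.0) < 0.02

    def test_constant_index_rejected(self):
        rng = np.random.default_rng(8)
        _, out = make_censored(rng, 30)
        with pytest.raises(ValueError):
            evaluation.calibration_slope(np.ones(30), out)


class TestCalibrationQuartiles:
    def test_homogeneous_predictions_share_mean(self):
        rng = np.random.default_rng(9)
        _, out = make_censored(rng, 40)
        table = evaluation.calibration_quartiles(np.full(40, 0.6), out, 1.0)
        np.testing.assert_allclose(table[:, 0], 0.6)

    def test_well_calibrated_model_tracks_observed(self):
        cfg = ScenarioConfig(n=4000, p=6, signal="weak", seed=23)
        sim = gen_dataset(cfg)
        fit = coxcore.fit_cox(sim.X.values, sim.outcome)
        pred = evaluation.predict_survival(fit, sim.X.values, sim.outcome,
                                           sim.X.values, 2.0)
        table = evaluation.calibration_quartiles(pred, sim.outcome, 2.0)
        ok = ~np.isnan(table[:, 1])
        assert ok.sum() >= 3
        assert np.max(np.abs(table[ok, 0] - table[ok, 1])) < 0.05

    def test_sign_reversal_reverses_bins(self):
        rng = np.random.default_rng(10)
        _, out = make_censored(rng, 48)
        pred = np.linspace(0.02, 0.98, 48)
        a = evaluation.calibration_quartiles(pred, out, 1.0)
        b = evaluation.calibration_quartiles(1 - pred, out, 1.0)
        np.testing.assert_allclose(b[:, 0], (1 - a[:, 0])[::-1], atol=1e-12)


class TestBootstrapOptimism:
    def test_data_ignoring_rule_has_no_optimism(self):
        rng = np.random.default_rng(11)
        x, out = make_censored(rng, 150, beta=0.5)

        def fixed_pipeline(X, outcome, seed):
            return lambda Xn: Xn[:, 0]

        opt, c_corr, failed = evaluation.bootstrap_optimism(
            x[:, None], out, fixed_pipeline, B=30, seed=0)
        assert abs(opt) < 0.02
        assert failed == 0

    def test_overfit_pipeline_has_positive_optimism(self):
        rng = np.random.default_rng(12)
        n = 60
        X = rng.standard_normal((n, 40))
        _, out = make_censored(rng, n)  # outcome independent of X

        def greedy_pipeline(Xb, yb, seed):
            fit = coxcore.fit_cox(Xb[:, :20], yb, max_iter=25)
            return lambda Xn: Xn[:, :20] @ fit.beta

        opt, c_corr, _ = evaluation.bootstrap_optimism(
            X, out, greedy_pipeline, B=30, seed=1)
        assert opt > 0.05
        assert c_corr < 0.75
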