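import copy

import numpy as np
import pytest
from scipy.special import expit, logit

import cariesim as cs
from cariesim.errors import CalibrationError, ConfigurationError
from cariesim.natural_history import (MAX_RISK_AGE, band_index,
                                      simulate_band_prevalence)

from conftest import make_demo, single_individual, zeroed_risk_model


class TestAnnualCariesProb:
    def test_all_coefficients_zero_gives_half(self):
        pop = single_individual(age=8)
        rm = zeroed_risk_model()
        assert cs.annual_caries_prob(pop, rm, 0.0)[0] == pytest.approx(0.5)

    def test_intercept_logit_identity(self):
        pop = single_individual(age=8)
        rm = zeroed_risk_model(age_logit=[logit(0.2)] * 20)
        assert cs.annual_caries_prob(pop, rm, 0.0)[0] == pytest.approx(0.2)

    def test_protective_odds_ratio_shift(self):
        # hand-computed logit arithmetic: expit(logit(0.2) + ln 0.46)
        pop = single_individual(age=8)
        rm = zeroed_risk_model(age_logit=[logit(0.2)] * 20)
        expected = expit(logit(0.2) + np.log(0.46))
        got = cs.annual_caries_prob(pop, rm, np.log(0.46))[0]
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.10314, abs=1e-5)

    def test_monotone_decreasing_in_protective_shift(self):
        pop = single_individual(age=8)
        rm = zeroed_risk_model(age_logit=[logit(0.3)] * 20)
        probs = [cs.annual_caries_prob(pop, rm, s)[0]
                 for s in (0.0, -0.2, -0.5, -1.0)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_no_risk_past_max_age(self):
        pop = single_individual(age=MAX_RISK_AGE + 1)
        rm = zeroed_risk_model()
        assert cs.annual_caries_prob(pop, rm, 0.0)[0] == 0.0

    def test_saturates_smoothly(self):
        pop = single_individual(age=8)
        rm = zeroed_risk_model(age_logit=[60.0] * 20)
        assert cs.annual_caries_prob(pop, rm, 0.0)[0] == pytest.approx(1.0)
        rm.age_logit = [-60.0] * 20
        assert cs.annual_caries_prob(pop, rm, 0.0)[0] == pytest.approx(0.0)


class TestStepDisease:
    def test_zero_probabilities_only_ages(self):
        pop = single_individual(age=8)
        rm = zeroed_risk_model(age_logit=[-60.0] * 20)
        before = pop.to_frame().copy()
        cs.step_disease(pop, rm, np.zeros(1), 0.0, cycle=0, seed=1)
        after = pop.to_frame()
        assert after.loc[0, "age"] == before.loc[0, "age"] + 1
        for col in ("caries_events", "untreated", "abscess_count",
                    "teeth_lost", "alive"):
            assert after.loc[0, col] == before.loc[0, col]

    def test_forced_transitions(self):
        # caries prob ~1, untreated prob 1, abscess prob 1: event accrues,
        # goes untreated, and the complication draw fires the same cycle
        pop = single_individual(age=8)
        rm = zeroed_risk_model(age_logit=[60.0] * 20, p_untreated_no_util=1.0,
                               p_abscess=1.0, p_toothloss=1.0)
        ev = cs.step_disease(pop, rm, np.zeros(1), 0.0, cycle=0, seed=1)
        assert pop.caries_events[0] == 1
        assert pop.untreated[0]
        assert pop.abscess_count[0] == 1
        assert pop.teeth_lost[0] == 1
        assert ev.new_events[0] and not ev.new_treated[0]

    def test_binomial_oracle_incidence(self, default_params):
        demo = default_params.demographics
        pop = cs.generate_population(10000, demo, seed=3)
        pop.util_prob[:] = 0.0
        pop.baseline_assigned = True
        rm = zeroed_risk_model(age_logit=[logit(0.3)] * 20)
        ev = cs.step_disease(pop, rm, pop.util_prob, 0.0, cycle=0, seed=9)
        frac = ev.new_events.mean()
        sd = np.sqrt(0.3 * 0.7 / pop.n)
        assert abs(frac - 0.3) <= 3 * sd

    def test_utilization_converts_untreated(self):
        pop = single_individual(age=8)
        pop.caries_events[:] = 1
        pop.untreated[:] = True
        rm = zeroed_risk_model(age_logit=[-60.0] * 20)
        ev = cs.step_disease(pop, rm, np.ones(1), 0.0, cycle=0, seed=1)
        assert ev.conversions[0]
        assert not pop.untreated[0]

    def test_complication_counters_bounded(self, calibrated_params, pop5k):
        pop = pop5k.copy()
        rm = calibrated_params.risk
        for t in range(10):
            cs.step_disease(pop, rm, pop.util_prob, 0.0, cycle=t, seed=17)
            assert (pop.teeth_lost <= pop.caries_events).all()
            assert (pop.abscess_count <= pop.caries_events).all()

    def test_counters_monotone_nondecreasing(self, calibrated_params, pop5k):
        pop = pop5k.copy()
        prev = (pop.caries_events.copy(), pop.abscess_count.copy(),
                pop.teeth_lost.copy())
        for t in range(10):
            cs.step_disease(pop, calibrated_params.risk, pop.util_prob, 0.0,
                            cycle=t, seed=23)
            assert (pop.caries_events >= prev[0]).all()
            assert (pop.abscess_count >= prev[1]).all()
            assert (pop.teeth_lost >= prev[2]).all()
            prev = (pop.caries_events.copy(), pop.abscess_count.copy(),
                    pop.teeth_lost.copy())

    def test_age_advances_by_one_while_alive(self, calibrated_params, pop5k):
        pop = pop5k.copy()
        age0 = pop.age.copy()
        alive0 = pop.alive.copy()
        cs.step_disease(pop, calibrated_params.risk, pop.util_prob, 0.0,
                        cycle=0, seed=31)
        assert (pop.age[alive0] == age0[alive0] + 1).all()

    def test_protective_shift_reduces_expected_incidence(self, calibrated_params,
                                                         pop5k):
        # expectation over >= 20 seeds under common random numbers
        diffs = []
        for seed in range(20):
            totals = []
            for shift in (0.0, -0.4):
                pop = pop5k.copy()
                total = 0
                for t in range(5):
                    ev = cs.step_disease(pop, calibrated_params.risk,
                                         pop.util_prob, shift, cycle=t, seed=seed)
                    total += ev.new_events.sum()
                totals.append(total)
            diffs.append(totals[0] - totals[1])
        assert np.mean(diffs) > 0
        # pointwise nesting under CRN: protective shift never adds events
        assert min(diffs) >= 0

    def test_mortality_rate_bands(self):
        rm = cs.RiskModel()
        rates = rm.mortality_rate(np.array([0, 1, 4, 5, 14, 15, 19, 20, 29]))
        assert rates[0] == 0.0056
        assert rates[1] == rates[2] == 0.00025
        assert rates[3] == rates[4] == 0.00015
        assert rates[5] == rates[6] == 0.0006
        assert rates[7] == rates[8] == 0.0009


class TestCalibrate:
    def test_fixed_point_multipliers_stay_near_zero(self, default_params, pop5k):
        # targets generated by the model itself: recovered adjustments ~ 0
        rm = copy.deepcopy(default_params.risk)
        targets = simulate_band_prevalence(pop5k, rm, 6, disease_seed=13)
        fitted, report = cs.calibrate(
            rm, targets, pop5k,
            cs.CalibrationSettings(horizon=6, disease_seed=13, tolerance=1e-4))
        for g, m in fitted.calibration.items():
            assert abs(m) < 0.05
        assert fitted.calibrated

    def test_deterministic_given_seeds(self, default_params, pop5k):
        rm = copy.deepcopy(default_params.risk)
        settings = cs.CalibrationSettings(horizon=6, disease_seed=2)
        f1, r1 = cs.calibrate(rm, default_params.calibration_targets, pop5k, settings)
        f2, r2 = cs.calibrate(rm, default_params.calibration_targets, pop5k, settings)
        assert f1.calibration == f2.calibration
        assert r1.equals(r2)

    def test_achieves_targets_within_tolerance(self, calibrated_params, pop20k):
        prev = simulate_band_prevalence(pop20k, calibrated_params.risk, 10,
                                        disease_seed=1)
        for g, t in calibrated_params.calibration_targets.items():
            assert abs(prev[g] - t) <= 0.005 + 1e-12

    def test_unreachable_target_raises_with_residual(self, default_params, pop5k):
        rm = copy.deepcopy(default_params.risk)
        targets = {"0-5": 0.001, "6-12": 0.5, "13-19": 0.55}
        with pytest.raises(CalibrationError) as err:
            cs.calibrate(rm, targets, pop5k,
                         cs.CalibrationSettings(horizon=6, disease_seed=2))
        assert err.value.best_residual is not None
        assert err.value.best_residual > 0

    def test_invalid_target_rejected(self, default_params, pop5k):
        with pytest.raises(ConfigurationError):
            cs.calibrate(default_params.risk, {"0-5": 1.5, "6-12": 0.5,
                                               "13-19": 0.5}, pop5k)

    def test_requires_baseline_assignment(self, default_params):
        pop = cs.generate_population(500, default_params.demographics, seed=1)
        with pytest.raises(ConfigurationError, match="baseline"):
            cs.calibrate(default_params.risk,
                         default_params.calibration_targets, pop)


def test_band_index_boundaries():
    idx = band_index(np.array([0, 1, 2, 5, 6, 12, 13, 19, 20]))
    assert idx.tolist() == [-1, -1, 0, 0, 1, 1, 2, 2, -1]
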