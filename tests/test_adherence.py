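"""Adherence endpoint, regression fits, polypill RR and cessation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polypillsim.adherence import (AdherenceModel, AdherenceRR,
                                   classify_adherent, estimate_polypill_rr,
                                   fit_adherence_model, prob_adherent,
                                   sample_cessation_time,
                                   simulate_adherence_trial,
                                   TRIAL_PREDICTORS)
from polypillsim.errors import ContractError, DataError, FittingError

from conftest import make_individual


class TestEndpoint:
    @pytest.mark.parametrize("statin,aspirin,ahts,expected", [
        (4, 4, [4, 4], True),          # all components at the threshold
        (3, 7, [7, 7], False),         # statin fails the conjunction
        (7, 3, [7, 7], False),         # antiplatelet fails
        (7, 7, [7, 3], False),         # only one AHT at >=4 days
        (7, 7, [3, 3, 7, 7], True),    # two of four AHTs suffice
        (0, 0, [0, 0], False),
        (7, 7, [7], False),            # a single AHT agent can never qualify
    ])
    def test_conjunction_rule(self, statin, aspirin, ahts, expected):
        assert classify_adherent(statin, aspirin, ahts) is expected

    @pytest.mark.parametrize("bad", [-1, 8, 3.5])
    def test_rejects_counts_outside_week(self, bad):
        with pytest.raises(DataError):
            classify_adherent(bad, 4, [4, 4])

    @given(st.integers(0, 7), st.integers(0, 7),
           st.lists(st.integers(0, 7), min_size=0, max_size=5))
    def test_adherence_never_easier_than_each_component(self, s, a, ahts):
        if classify_adherent(s, a, ahts):
            assert s >= 4 and a >= 4
            assert sum(1 for d in ahts if d >= 4) >= 2


class TestUsualCareModel:
    def test_intercept_only_closed_form_mle(self):
        import pandas as pd
        y = np.zeros(1000)
        y[:700] = 1.0
        df = pd.DataFrame({"adherent": y})
        model = fit_adherence_model(df, predictors=[])
        assert model.intercept == pytest.approx(math.log(0.7 / 0.3), abs=1e-6)

    def test_known_coefficients_recovered(self):
        truth = AdherenceModel(intercept=0.2,
                               weights={"age_centered": 0.25, "female": -0.10,
                                        "deprivation": -0.18})
        df = simulate_adherence_trial(10_000, truth, true_rr=1.0, seed=5)
        fitted = fit_adherence_model(df[df.arm == "usual"], TRIAL_PREDICTORS)
        assert fitted.intercept == pytest.approx(0.2, abs=3 * fitted.stderr["const"])
        for name, w in truth.weights.items():
            assert fitted.weights[name] == pytest.approx(
                w, abs=3 * fitted.stderr[name])

    def test_single_class_outcome_rejected(self):
        import pandas as pd
        df = pd.DataFrame({"adherent": np.ones(50)})
        with pytest.raises(FittingError, match="single class"):
            fit_adherence_model(df, predictors=[])

    def test_predictions_are_probabilities(self):
        model = AdherenceModel(intercept=3.0, weights={"age_centered": 2.0})
        for age in (20.0, 60.0, 95.0):
            p = prob_adherent(make_individual(age=age), model, "usual",
                              AdherenceRR())
            assert 0.0 <= p <= 1.0


class TestArmModification:
    def test_null_rr_leaves_probability_unchanged(self, default_params):
        ind = make_individual()
        model = default_params.adherence_model
        rr1 = AdherenceRR(rr=1.0, ci_low=1.0, ci_high=1.0)
        assert prob_adherent(ind, model, "polypill", rr1) == \
            prob_adherent(ind, model, "usual", rr1)

    def test_polypill_probability_capped_at_one(self):
        model = AdherenceModel(intercept=math.log(0.8 / 0.2))  # p = 0.8
        rr = AdherenceRR(rr=1.4, ci_low=1.2, ci_high=1.6)
        assert prob_adherent(make_individual(), model, "polypill", rr) == 1.0

    def test_usual_arm_ignores_rr_entirely(self):
        model = AdherenceModel(intercept=0.0)   # p = 0.5
        huge = AdherenceRR(rr=1.9, ci_low=1.5, ci_high=2.4)
        assert prob_adherent(make_individual(), model, "usual", huge) == 0.5

    def test_polypill_dominates_usual_when_rr_above_one(self, default_params):
        rr = AdherenceRR(rr=1.3, ci_low=1.1, ci_high=1.5)
        for age in (45.0, 62.0, 80.0):
            ind = make_individual(age=age)
            assert prob_adherent(ind, default_params.adherence_model,
                                 "polypill", rr) >= \
                prob_adherent(ind, default_params.adherence_model, "usual", rr)


class TestPolypillRR:
    def test_identical_arms_give_null_rr(self):
        model = AdherenceModel(intercept=0.3)
        trial = simulate_adherence_trial(3000, model, true_rr=1.0, seed=2)
        est = estimate_polypill_rr(trial)
        se_log = (math.log(est.ci_high) - math.log(est.rr)) / 1.959963984540054
        assert abs(math.log(est.rr)) < 3 * se_log

    def test_ci_brackets_estimate(self):
        model = AdherenceModel(intercept=0.2)
        for seed in range(5):
            est = estimate_polypill_rr(
                simulate_adherence_trial(500, model, true_rr=1.3, seed=seed))
            assert est.ci_low <= est.rr <= est.ci_high

    def test_simulation_oracle_mean_within_two_percent(self, default_params):
        model = default_params.adherence_model
        estimates = [estimate_polypill_rr(
            simulate_adherence_trial(1000, model, true_rr=1.3, seed=s)).rr
            for s in range(100)]
        assert np.mean(estimates) == pytest.approx(1.3, rel=0.02)

    def test_zero_adherent_arm_rejected(self):
        import pandas as pd
        trial = pd.DataFrame({
            "arm": ["usual"] * 10 + ["polypill"] * 10,
            "adherent": [0] * 10 + [1] * 10})
        with pytest.raises(FittingError):
            estimate_polypill_rr(trial)


class TestCessation:
    def test_zero_hazard_never_ceases(self):
        model = AdherenceModel(cessation_hazard=0.0)
        assert sample_cessation_time(model, np.random.default_rng(0)) == math.inf

    def test_mean_time_matches_hazard(self):
        model = AdherenceModel(cessation_hazard=0.1)
        rng = np.random.default_rng(3)
        draws = np.array([sample_cessation_time(model, rng)
                          for _ in range(100_000)])
        se = 10.0 / math.sqrt(draws.size)
        assert abs(draws.mean() - 10.0) < 3 * se

    def test_negative_hazard_rejected(self):
        with pytest.raises(ContractError):
            sample_cessation_time(AdherenceModel(cessation_hazard=-1.0),
                                  np.random.default_rng(0))

    def test_cessation_removes_treatment_effect(self):
        """After cessation the CVD hazard reverts to baseline."""
        from polypillsim.analysis import individual_rng
        from polypillsim.config import ScenarioConfig
        from polypillsim.engine import EventType, simulate_individual
        from conftest import constant_hazard_params

        params = constant_hazard_params(cvd_hazard=0.05, mortality_q=0.0,
                                        cessation_hazard=2.0, adherent=True)
        # protective statin effect while adherent
        params.treatment_effects.rr_cvd_statin = 0.5
        scenario = ScenarioConfig(arm="usual", master_seed=1)
        ceased = 0
        for i in range(200):
            traj = simulate_individual(make_individual(id=i, age=60.0),
                                       scenario, params,
                                       individual_rng(1, i))
            times = {e.type: e.time for e in traj.events}
            if EventType.CESSATION in times:
                ceased += 1
                # exposure after cessation is off-treatment, non-adherent
                t_cess = times[EventType.CESSATION]
                for seg in traj.exposure:
                    if seg.start >= t_cess:
                        assert not seg.on_treatment and not seg.adherent
        assert ceased > 100   # hazard 2/yr: almost everyone stops early
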