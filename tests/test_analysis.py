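"""Incremental analysis, PSA machinery and convergence diagnostics."""

import math

import numpy as np
import pytest

from polypillsim.analysis import (ArmResult, CEAResult, PSASpec,
                                  bootstrap_indices, ceac_from_cloud,
                                  convergence_check, icer_and_nmb, run_psa,
                                  run_scenarios, sensitivity_overlay)
from polypillsim.economics import DiscountedOutcome
from polypillsim.errors import ConfigurationError

from conftest import null_effect_params


def fake_arm(arm, costs, qalys):
    outcomes = [DiscountedOutcome(c, q, c, q) for c, q in zip(costs, qalys)]
    return ArmResult(arm=arm, outcomes=outcomes, trajectories=[])


class TestIcerAndNmb:
    def test_icer_arithmetic(self):
        r = icer_and_nmb(fake_arm("usual", [1000.0], [1.0]),
                         fake_arm("polypill", [2000.0], [1.1]), (20000.0,))
        assert r.delta_cost == pytest.approx(1000.0)
        assert r.delta_qalys == pytest.approx(0.1)
        assert r.icer == pytest.approx(10_000.0)
        assert r.dominance is None
        assert r.nmb[20000.0] == pytest.approx(20000 * 0.1 - 1000.0)

    def test_dominant_label_no_ratio(self):
        r = icer_and_nmb(fake_arm("usual", [1000.0], [1.0]),
                         fake_arm("polypill", [950.0], [1.2]), (20000.0,))
        assert r.dominance == "dominant"
        assert r.icer is None

    def test_dominated_label(self):
        r = icer_and_nmb(fake_arm("usual", [1000.0], [1.0]),
                         fake_arm("polypill", [1100.0], [0.9]), (20000.0,))
        assert r.dominance == "dominated"
        assert r.icer is None

    def test_zero_delta_e_keeps_nmb(self):
        r = icer_and_nmb(fake_arm("usual", [1000.0], [1.0]),
                         fake_arm("polypill", [1500.0], [1.0]), (20000.0,))
        assert r.icer is None
        assert r.nmb[20000.0] == pytest.approx(-500.0)

    def test_nmb_zero_exactly_at_icer(self):
        r = icer_and_nmb(fake_arm("usual", [0.0], [0.0]),
                         fake_arm("polypill", [1000.0], [0.1]),
                         (10_000.0,))
        assert r.icer == pytest.approx(10_000.0)
        assert r.nmb[10_000.0] == pytest.approx(0.0, abs=1e-9)


class TestScenarioRuns:
    def test_null_scenario_exact_equivalence(self, small_cohort):
        params = null_effect_params()
        arms = run_scenarios(small_cohort, params, master_seed=5)
        r = icer_and_nmb(arms["usual"], arms["polypill"], (20000.0,))
        assert r.delta_cost == 0.0
        assert r.delta_qalys == 0.0

    def test_rerun_is_bit_identical(self, small_cohort, default_params):
        a = run_scenarios(small_cohort, default_params, master_seed=6)
        b = run_scenarios(small_cohort, default_params, master_seed=6)
        for arm in ("usual", "polypill"):
            assert [o.cost for o in a[arm].outcomes] == \
                [o.cost for o in b[arm].outcomes]
            assert [o.qalys for o in a[arm].outcomes] == \
                [o.qalys for o in b[arm].outcomes]

    def test_polypill_adherence_dominates_pointwise(self, small_cohort,
                                                    default_params):
        """With RR >= 1 and CRN, anyone adherent under usual care in the
        first period is adherent under the polypill too."""
        arms = run_scenarios(small_cohort, default_params, master_seed=7)
        for tu, tp in zip(arms["usual"].trajectories,
                          arms["polypill"].trajectories):
            if tu.exposure and tp.exposure and tu.exposure[0].adherent:
                assert tp.exposure[0].adherent


class TestPsa:
    def test_degenerate_psa_reproduces_base_case(self, small_cohort,
                                                 default_params):
        params = default_params
        spec = PSASpec(n_iterations=3,
                       distributions={
                           "treatment_effects.rr_cvd_statin": {"kind": "fixed"},
                           "costs.acute.stroke": {"kind": "fixed"}},
                       bootstrap=False, master_seed=8)
        res = run_psa(small_cohort[:50], spec, params)
        assert np.allclose(res.cloud, res.cloud[0])
        assert res.cloud[0, 0] == pytest.approx(res.base_case.delta_cost)
        assert res.cloud[0, 1] == pytest.approx(res.base_case.delta_qalys)

    def test_bootstrap_resample_size_equals_population(self):
        idx = bootstrap_indices(137, master_seed=1, iteration=4)
        assert idx.shape == (137,)
        assert idx.min() >= 0 and idx.max() < 137
        # with replacement: essentially surely some index repeats
        assert len(np.unique(idx)) < 137

    def test_unspecified_distribution_kind_rejected(self, small_cohort):
        spec = PSASpec(n_iterations=2,
                       distributions={"costs.acute.stroke": {"sd": 1.0}})
        with pytest.raises(ConfigurationError):
            run_psa(small_cohort[:10], spec, null_effect_params())

    def test_wider_prior_never_shrinks_delta_cost_spread(self, default_params,
                                                         small_cohort):
        pop = small_cohort[:40]

        def iqr(sigma):
            spec = PSASpec(
                n_iterations=100,
                distributions={"treatment_effects.rr_cvd_statin":
                               {"kind": "lognormal", "sigma": sigma}},
                bootstrap=False, master_seed=9)
            res = run_psa(pop, spec, default_params)
            q75, q25 = np.percentile(res.cloud[:, 0], [75, 25])
            return q75 - q25

        assert iqr(0.2) >= iqr(0.1)

    def test_ceac_non_decreasing_when_gains_positive(self):
        cloud = np.column_stack([np.random.default_rng(0).normal(100, 50, 200),
                                 np.abs(np.random.default_rng(1).normal(
                                     0.1, 0.02, 200))])
        wtps = [0.0, 1000.0, 5000.0, 20000.0, 100000.0]
        ceac = ceac_from_cloud(cloud, wtps)
        vals = [ceac[w] for w in wtps]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestConvergence:
    def test_constant_stream_stable(self):
        rep = convergence_check([5.0] * 20)
        assert rep.stable

    def test_half_width_shrinks_at_root_n(self):
        rng = np.random.default_rng(11)
        x = rng.normal(10.0, 2.0, 40_000)
        r1 = convergence_check(x[:10_000])
        r4 = convergence_check(x)
        ratio = r1.rel_half_width / r4.rel_half_width
        assert ratio == pytest.approx(2.0, rel=0.1)

    def test_zero_tolerance_flagged_not_looped(self):
        rep = convergence_check([1.0, 2.0, 3.0], rel_tol=0.0)
        assert not rep.stable and rep.flagged
        assert math.isinf(rep.recommended_n)

    def test_recommended_n_reaches_tolerance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(100.0, 10.0, 50)
        rep = convergence_check(x, rel_tol=0.01)
        assert rep.recommended_n > 50


class TestSensitivityOverlays:
    def test_higher_polypill_price_raises_cost_not_qalys(self, default_params,
                                                         small_cohort):
        pop = small_cohort[:60]
        cheap = sensitivity_overlay(default_params, "polypill_price", 50.0)
        dear = sensitivity_overlay(default_params, "polypill_price", 500.0)
        a = run_scenarios(pop, cheap, master_seed=13)
        b = run_scenarios(pop, dear, master_seed=13)
        assert b["polypill"].mean_cost > a["polypill"].mean_cost
        assert b["polypill"].mean_qalys == a["polypill"].mean_qalys
        assert b["usual"].mean_cost == a["usual"].mean_cost

    def test_unknown_dial_rejected(self, default_params):
        with pytest.raises(ConfigurationError, match="unknown sensitivity"):
            sensitivity_overlay(default_params, "nonsense", 1.0)
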