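import hypothesis
import pytest

from polypillsim.config import ParameterSet
from polypillsim.mortality import LifeTable
from polypillsim.population import Individual, MedicationProfile, PriorEvent
from polypillsim.risk import RiskCoefficients

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[hypothesis.HealthCheck.too_slow])
hypothesis.settings.load_profile("ci")


def make_individual(**overrides) -> Individual:
    """A typical high-risk man unless overridden."""
    base = dict(
        id=0, age=62.0, sex="male", ethnicity="white", smoking="non",
        sbp=140.0, chol_ratio=4.2, bmi=28.0, deprivation=0.0,
        diabetes=False, family_history_chd=False, treated_hypertension=False,
        cvd_history=[], meds=MedicationProfile())
    base.update(overrides)
    return Individual(**base)


def with_prior_mi(**overrides) -> Individual:
    overrides.setdefault("cvd_history", [PriorEvent("mi", 2.0)])
    return make_individual(**overrides)


def flat_life_table(q: float, age_min: int = 18, age_max: int = 100) -> LifeTable:
    qs = [q] * (age_max - age_min + 1)
    return LifeTable(age_min, {"male": list(qs), "female": list(qs)})


def zero_coeffs(name: str, horizon: float,
                baseline_survival: float = 1.0) -> RiskCoefficients:
    """Engine with no covariate terms; risk = 1 - baseline_survival."""
    return RiskCoefficients(engine_name=name, horizon=horizon,
                            baseline_survival=baseline_survival, terms=())


def constant_hazard_params(cvd_hazard: float = 0.0,
                           diabetes_hazard: float = 0.0,
                           gi_hazard: float = 0.0,
                           hf_rate: float = 0.0,
                           mortality_q: float = 0.0,
                           cessation_hazard: float = 0.0,
                           adherent: bool = False) -> ParameterSet:
    """Parameter set with flat, covariate-free hazards for oracle tests.

    All treatment relative risks are 1 and the cough probability is 0, so
    adherence has no effect on event rates; the adherence intercept
    controls whether people count as adherent at all.
    """
    import math
    p = ParameterSet.from_dict({
        "treatment_effects": {
            "rr_cvd_statin": 1.0, "rr_cvd_aht": 1.0, "rr_cvd_aspirin": 1.0,
            "rr_diabetes_tx": 1.0, "rr_gi_bleed_aspirin": 1.0,
            "p_cough_acei": 0.0, "rr_hf_aht": 1.0},
        "adherence_rr": {"rr": 1.0, "ci_low": 1.0, "ci_high": 1.0},
        "adherence_model": {
            "intercept": 50.0 if adherent else -50.0, "weights": {},
            "cessation_hazard": cessation_hazard},
        "case_fatality": {"stroke_lt75": 0.0, "stroke_ge75": 0.0,
                          "mi_bands": [0.0] * 5},
        "baseline_gi_hazard": gi_hazard,
    })
    p.primary_coeffs = zero_coeffs("primary_cvd", 10.0,
                                   math.exp(-cvd_hazard * 10.0))
    p.secondary_coeffs = zero_coeffs("secondary_cvd", 5.0,
                                     math.exp(-cvd_hazard * 5.0))
    p.diabetes_coeffs = zero_coeffs("diabetes", 10.0,
                                    math.exp(-diabetes_hazard * 10.0))
    from polypillsim.effects import AgeRateTable
    p.hf_baseline = AgeRateTable(ages=(18.0, 100.0), rates=(hf_rate, hf_rate))
    p.life_table = flat_life_table(mortality_q)
    return p


def null_effect_params() -> ParameterSet:
    """Default parameters but with every treatment effect and the
    adherence RR set to null (arms become identical under CRN)."""
    return ParameterSet.from_dict({
        "treatment_effects": {
            "rr_cvd_statin": 1.0, "rr_cvd_aht": 1.0, "rr_cvd_aspirin": 1.0,
            "rr_diabetes_tx": 1.0, "rr_gi_bleed_aspirin": 1.0,
            "p_cough_acei": 0.0, "rr_hf_aht": 1.0},
        "adherence_rr": {"rr": 1.0, "ci_low": 1.0, "ci_high": 1.0},
    })


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    p = ParameterSet()
    p.validate()
    return p


@pytest.fixture(scope="session")
def small_cohort(default_params):
    from polypillsim import population, risk
    spec = population.PopulationSpec(n=300, seed=11)
    return population.build_cohort(
        200, spec,
        lambda ind: risk.five_year_risk(ind, default_params.primary_coeffs),
        threshold=default_params.inclusion_threshold)
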