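"""Parameter schema, defaults, validation and reproducible configuration IO.

:class:`ParameterSet` collects every model input: the three risk-engine
coefficient tables, the heart-failure incidence table, the CVD event-type
split, treatment effects, the adherence model and relative risk, case
fatality, the life table, costs, utilities, and the structural scalars
(discount rate 3.5%/year, age cap 100, 10-year risk-update interval,
15% 5-year inclusion threshold).

Configuration files are YAML (or JSON, a YAML subset): any subset of
fields overrides the packaged defaults; tables can be inlined or pointed
at CSV files in the formats owned by their modules. Validation aggregates
every problem into one :class:`~polypillsim.errors.ValidationError` rather
than stopping at the first. A run manifest (master seed + SHA-256 digest
of the resolved parameters) is enough to reproduce any result bit for bit.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .adherence import AdherenceModel, AdherenceRR
from .economics import CostTable, UtilityTable
from .effects import AgeRateTable, TreatmentEffects
from .errors import ConfigurationError, ValidationError
from .mortality import CaseFatality, LifeTable
from .risk import RiskCoefficients, Term, coefficients_from_csv

logger = logging.getLogger("polypillsim")

DEFAULT_DISCOUNT_RATE = 0.035
DEFAULT_AGE_CAP = 100.0
DEFAULT_UPDATE_INTERVAL = 10.0
DEFAULT_INCLUSION_THRESHOLD = 0.15


# ---------------------------------------------------------------------------
# packaged illustrative defaults

def _default_primary() -> RiskCoefficients:
    """Primary CVD engine (QRISK2-style functional form, illustrative
    weights; drop in a published coefficient CSV for the real thing)."""
    return RiskCoefficients(
        engine_name="primary_cvd", horizon=10.0, baseline_survival=0.95,
        terms=(
            Term("age", "age_centered", 0.55),
            Term("age_sq", "age_centered_sq", 0.03),
            Term("female", "female", -0.35),
            Term("sbp", "sbp_centered", 0.22),
            Term("chol_ratio", "chol_ratio_centered", 0.15),
            Term("bmi", "bmi_centered", 0.10),
            Term("deprivation", "deprivation", 0.12),
            Term("smoker_ex", "smoker_ex", 0.20),
            Term("smoker_current", "smoker_current", 0.55),
            Term("south_asian", "ethnicity_south_asian", 0.30),
            Term("black", "ethnicity_black", -0.10),
            Term("diabetes", "diabetes", 0.60),
            Term("family_history", "family_history_chd", 0.35),
            Term("treated_ht", "treated_hypertension", 0.30),
        ))


def _default_secondary() -> RiskCoefficients:
    """Recurrent-event engine for established CVD (REACH-style composite;
    horizon 5 years by default, configurable)."""
    return RiskCoefficients(
        engine_name="secondary_cvd", horizon=5.0, baseline_survival=0.82,
        terms=(
            Term("age", "age_centered", 0.30),
            Term("female", "female", -0.15),
            Term("diabetes", "diabetes", 0.40),
            Term("smoker_current", "smoker_current", 0.30),
            Term("n_prior_events", "n_prior_events", 0.25),
            Term("prior_mi", "prior_mi", 0.15),
            Term("prior_stroke", "prior_stroke", 0.20),
        ))


def _default_diabetes() -> RiskCoefficients:
    """Incident type 2 diabetes engine (QDiabetes-style form)."""
    return RiskCoefficients(
        engine_name="diabetes", horizon=10.0, baseline_survival=0.93,
        terms=(
            Term("age", "age_centered", 0.25),
            Term("female", "female", -0.10),
            Term("bmi", "bmi_centered", 0.55),
            Term("deprivation", "deprivation", 0.12),
            Term("smoker_current", "smoker_current", 0.20),
            Term("south_asian", "ethnicity_south_asian", 0.80),
            Term("black", "ethnicity_black", 0.40),
            Term("family_history", "family_history_chd", 0.15),
            Term("treated_ht", "treated_hypertension", 0.30),
        ))


def _default_hf_table() -> AgeRateTable:
    """Heart-failure incidence per person-year, rising steeply with age
    (illustrative, shaped like published incidence-rate studies)."""
    return AgeRateTable(
        ages=(18.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 100.0),
        rates=(0.0001, 0.0004, 0.001, 0.002, 0.005, 0.012, 0.022, 0.030))


def _default_life_table() -> LifeTable:
    """Synthetic Gompertz-Makeham life table for ages 18-100 by sex.

    q(age) = 1 - exp(-(A + B * exp(c * (age - 0)))) with sex-specific B;
    a stand-in shaped like a national (England & Wales) life table, NOT
    real published rates. Replace via the ``life_table`` CSV to use ONS
    data.
    """
    import math
    A, c = 0.00015, 0.09
    B = {"male": 3.5e-5, "female": 2.0e-5}
    qx = {}
    for sex, b in B.items():
        qs = []
        for age in range(18, 101):
            h = A + b * math.exp(c * age)
            qs.append(1.0 - math.exp(-h))
        qx[sex] = qs
    return LifeTable(18, qx)


def _default_adherence_model() -> AdherenceModel:
    return AdherenceModel(
        intercept=0.2,
        weights={"age_centered": 0.25, "female": -0.10, "deprivation": -0.18},
        cessation_hazard=0.05)


def default_rel_incidence() -> dict:
    """Share of acute CVD events by type (TIA, stroke, MI, angina),
    shaped like population-based incidence studies (illustrative)."""
    return {"tia": 0.22, "stroke": 0.32, "mi": 0.28, "angina": 0.18}


@dataclass
class ParameterSet:
    primary_coeffs: RiskCoefficients = field(default_factory=_default_primary)
    secondary_coeffs: RiskCoefficients = field(default_factory=_default_secondary)
    diabetes_coeffs: RiskCoefficients = field(default_factory=_default_diabetes)
    hf_baseline: AgeRateTable = field(default_factory=_default_hf_table)
    rel_incidence: dict = field(default_factory=default_rel_incidence)
    treatment_effects: TreatmentEffects = field(default_factory=TreatmentEffects)
    adherence_model: AdherenceModel = field(default_factory=_default_adherence_model)
    adherence_rr: AdherenceRR = field(default_factory=lambda: AdherenceRR(
        rr=1.3, ci_low=1.15, ci_high=1.47))
    case_fatality: CaseFatality = field(default_factory=CaseFatality)
    life_table: LifeTable = field(default_factory=_default_life_table)
    costs: CostTable = field(default_factory=CostTable)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    baseline_gi_hazard: float = 0.001          # per year, untreated
    discount_rate: float = DEFAULT_DISCOUNT_RATE
    age_cap: float = DEFAULT_AGE_CAP
    risk_update_interval: float = DEFAULT_UPDATE_INTERVAL
    inclusion_threshold: float = DEFAULT_INCLUSION_THRESHOLD

    def validate(self) -> None:
        problems: list[str] = []

        def check(obj, path):
            try:
                obj.validate()
            except ConfigurationError as exc:
                problems.append(f"{path}: {exc}")
            except Exception as exc:   # ContractError etc.
                problems.append(f"{path}: {exc}")

        check(self.primary_coeffs, "primary_coeffs")
        check(self.secondary_coeffs, "secondary_coeffs")
        check(self.diabetes_coeffs, "diabetes_coeffs")
        check(self.hf_baseline, "hf_baseline")
        check(self.treatment_effects, "treatment_effects")
        check(self.adherence_model, "adherence_model")
        check(self.adherence_rr, "adherence_rr")
        check(self.case_fatality, "case_fatality")
        check(self.costs, "costs")
        check(self.utilities, "utilities")
        try:
            self.life_table._validate()
        except ConfigurationError as exc:
            problems.append(f"life_table: {exc}")

        keys = set(self.rel_incidence)
        if keys != {"tia", "stroke", "mi", "angina"}:
            problems.append(
                f"rel_incidence: keys must be tia/stroke/mi/angina, got {sorted(keys)}")
        else:
            vals = list(self.rel_incidence.values())
            if any(v < 0 for v in vals) or abs(sum(vals) - 1.0) > 1e-9:
                problems.append("rel_incidence: probabilities must be >= 0 "
                                "and sum to 1")
        if self.baseline_gi_hazard < 0:
            problems.append("baseline_gi_hazard: must be >= 0")
        if self.discount_rate < 0:
            problems.append("discount_rate: must be >= 0")
        if self.age_cap <= 0:
            problems.append("age_cap: must be > 0")
        if self.risk_update_interval <= 0:
            problems.append("risk_update_interval: must be > 0")
        if not 0.0 <= self.inclusion_threshold <= 1.0:
            problems.append("inclusion_threshold: must be in [0,1]")
        if problems:
            raise ValidationError(problems)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def coeffs(c: RiskCoefficients) -> dict:
            return {"engine_name": c.engine_name, "horizon": c.horizon,
                    "baseline_survival": c.baseline_survival,
                    "terms": [[t.name, t.transform, t.weight] for t in c.terms]}
        return {
            "primary_coeffs": coeffs(self.primary_coeffs),
            "secondary_coeffs": coeffs(self.secondary_coeffs),
            "diabetes_coeffs": coeffs(self.diabetes_coeffs),
            "hf_baseline": {"ages": list(self.hf_baseline.ages),
                            "rates": list(self.hf_baseline.rates)},
            "rel_incidence": dict(self.rel_incidence),
            "treatment_effects": dataclasses.asdict(self.treatment_effects),
            "adherence_model": {
                "intercept": self.adherence_model.intercept,
                "weights": dict(self.adherence_model.weights),
                "cessation_hazard": self.adherence_model.cessation_hazard,
                "link": self.adherence_model.link,
            },
            "adherence_rr": dataclasses.asdict(self.adherence_rr),
            "case_fatality": {"stroke_lt75": self.case_fatality.stroke_lt75,
                              "stroke_ge75": self.case_fatality.stroke_ge75,
                              "mi_bands": list(self.case_fatality.mi_bands)},
            "life_table": self.life_table.to_dict(),
            "costs": dataclasses.asdict(self.costs),
            "utilities": {
                "baseline": {sex: [list(b) for b in bands]
                             for sex, bands in self.utilities.baseline.items()},
                "decrements": dict(self.utilities.decrements),
                "transient": {k: list(v)
                              for k, v in self.utilities.transient.items()},
            },
            "baseline_gi_hazard": self.baseline_gi_hazard,
            "discount_rate": self.discount_rate,
            "age_cap": self.age_cap,
            "risk_update_interval": self.risk_update_interval,
            "inclusion_threshold": self.inclusion_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        base = cls()
        return _merge_into(base, d)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def __eq__(self, other) -> bool:
        return isinstance(other, ParameterSet) and self.to_dict() == other.to_dict()


def _coeffs_from_dict(d: dict, base: RiskCoefficients) -> RiskCoefficients:
    terms = base.terms
    if "terms" in d:
        terms = tuple(Term(str(n), str(tr), float(w)) for n, tr, w in d["terms"])
    return RiskCoefficients(
        engine_name=d.get("engine_name", base.engine_name),
        horizon=float(d.get("horizon", base.horizon)),
        baseline_survival=float(d.get("baseline_survival",
                                      base.baseline_survival)),
        terms=terms)


def _merge_into(base: ParameterSet, d: dict) -> ParameterSet:
    """Overlay a (possibly partial) config dict onto a ParameterSet."""
    known = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError([f"unknown parameter field {k!r}"
                               for k in sorted(unknown)])
    out = copy.deepcopy(base)
    for key in ("primary_coeffs", "secondary_coeffs", "diabetes_coeffs"):
        if key in d:
            setattr(out, key, _coeffs_from_dict(d[key], getattr(base, key)))
    if "hf_baseline" in d:
        out.hf_baseline = AgeRateTable(tuple(d["hf_baseline"]["ages"]),
                                       tuple(d["hf_baseline"]["rates"]))
    if "rel_incidence" in d:
        out.rel_incidence = {k: float(v) for k, v in d["rel_incidence"].items()}
    if "treatment_effects" in d:
        out.treatment_effects = dataclasses.replace(
            base.treatment_effects, **d["treatment_effects"])
    if "adherence_model" in d:
        am = d["adherence_model"]
        out.adherence_model = AdherenceModel(
            intercept=float(am.get("intercept", base.adherence_model.intercept)),
            weights={k: float(v) for k, v in am.get(
                "weights", base.adherence_model.weights).items()},
            cessation_hazard=float(am.get(
                "cessation_hazard", base.adherence_model.cessation_hazard)),
            link=am.get("link", "logit"))
    if "adherence_rr" in d:
        out.adherence_rr = AdherenceRR(**{k: float(v)
                                          for k, v in d["adherence_rr"].items()})
    if "case_fatality" in d:
        cfd = d["case_fatality"]
        out.case_fatality = CaseFatality(
            stroke_lt75=float(cfd.get("stroke_lt75",
                                      base.case_fatality.stroke_lt75)),
            stroke_ge75=float(cfd.get("stroke_ge75",
                                      base.case_fatality.stroke_ge75)),
            mi_bands=tuple(cfd.get("mi_bands", base.case_fatality.mi_bands)))
    if "life_table" in d:
        lt = d["life_table"]
        out.life_table = (LifeTable.from_csv(lt) if isinstance(lt, str)
                          else LifeTable.from_dict(lt))
    if "costs" in d:
        c = d["costs"]
        out.costs = CostTable(
            acute={**base.costs.acute, **c.get("acute", {})},
            annual_state={**base.costs.annual_state,
                          **c.get("annual_state", {})},
            annual_med={**base.costs.annual_med, **c.get("annual_med", {})},
            polypill_annual=c.get("polypill_annual",
                                  base.costs.polypill_annual),
            monitoring_annual=float(c.get("monitoring_annual",
                                          base.costs.monitoring_annual)),
            stopping_cost=float(c.get("stopping_cost",
                                      base.costs.stopping_cost)),
            currency_year=int(c.get("currency_year",
                                    base.costs.currency_year)))
    if "utilities" in d:
        u = d["utilities"]
        out.utilities = UtilityTable(
            baseline={sex: tuple((float(a), float(v)) for a, v in bands)
                      for sex, bands in u.get(
                          "baseline",
                          {s: [list(b) for b in bs]
                           for s, bs in base.utilities.baseline.items()}
                      ).items()},
            decrements={**base.utilities.decrements,
                        **u.get("decrements", {})},
            transient={**base.utilities.transient,
                       **{k: tuple(v) for k, v in u.get("transient", {}).items()}})
    for key in ("baseline_gi_hazard", "discount_rate", "age_cap",
                "risk_update_interval", "inclusion_threshold"):
        if key in d:
            setattr(out, key, float(d[key]))
        else:
            logger.debug("config: %s not given, default %s applied",
                         key, getattr(out, key))
    return out


@dataclass
class ScenarioConfig:
    """Run-level settings for one scenario arm (or an arm pair)."""

    arm: str = "usual"                      # "usual" | "polypill"
    polypill_version: str = "v1"            # composition metadata only
    master_seed: int = 0
    n: int = 1000
    wtp: tuple = (20000.0, 30000.0)         # willingness-to-pay, £/QALY
    output_dir: str | None = None

    def validate(self) -> None:
        problems = []
        if self.arm not in ("usual", "polypill"):
            problems.append(f"scenario.arm must be usual|polypill, got {self.arm!r}")
        if self.polypill_version not in ("v1", "v2"):
            problems.append("scenario.polypill_version must be v1 or v2")
        if self.n < 1:
            problems.append("scenario.n must be >= 1")
        if any(w < 0 for w in self.wtp):
            problems.append("scenario.wtp values must be >= 0")
        if problems:
            raise ValidationError(problems)


def load_and_validate(path) -> tuple[ParameterSet, ScenarioConfig]:
    """Read a YAML/JSON config, overlay onto defaults, validate everything.

    Top-level keys: ``parameters`` (partial ParameterSet overlay, tables
    inline or CSV paths relative to the config file), ``scenario``.
    Defaults for omitted fields are applied and logged at INFO level.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}

    params_d = dict(raw.get("parameters", {}))
    # table-by-CSV indirection, paths relative to the config file
    tables = raw.get("tables", {})
    if "life_table" in tables:
        params_d["life_table"] = LifeTable.from_csv(
            path.parent / tables["life_table"]).to_dict()
    if "risk_coefficients" in tables:
        engines = coefficients_from_csv(path.parent / tables["risk_coefficients"])
        for cfg_key, eng_key in (("primary_coeffs", "primary_cvd"),
                                 ("secondary_coeffs", "secondary_cvd"),
                                 ("diabetes_coeffs", "diabetes")):
            if eng_key in engines:
                c = engines[eng_key]
                params_d[cfg_key] = {
                    "engine_name": c.engine_name, "horizon": c.horizon,
                    "baseline_survival": c.baseline_survival,
                    "terms": [[t.name, t.transform, t.weight] for t in c.terms]}

    params = ParameterSet.from_dict(params_d)
    for key in ("discount_rate", "age_cap", "risk_update_interval",
                "inclusion_threshold"):
        if key not in params_d:
            logger.info("config %s: %s omitted; default %s applied",
                        path.name, key, getattr(params, key))
    params.validate()

    scen_d = raw.get("scenario", {})
    scenario = ScenarioConfig(**{k: (tuple(v) if k == "wtp" else v)
                                 for k, v in scen_d.items()})
    scenario.validate()
    return params, scenario


def write_resolved_config(params: ParameterSet, scenario: ScenarioConfig,
                          path) -> None:
    """Write the fully resolved configuration; reloading it reproduces the
    identical ParameterSet (serialization round trip)."""
    doc = {"parameters": params.to_dict(),
           "scenario": {"arm": scenario.arm,
                        "polypill_version": scenario.polypill_version,
                        "master_seed": scenario.master_seed,
                        "n": scenario.n,
                        "wtp": list(scenario.wtp)}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def write_manifest(path, params: ParameterSet, scenario: ScenarioConfig,
                   extra: dict | None = None) -> None:
    """Run manifest: master seed + parameter digest + package version."""
    from . import __version__
    doc = {"master_seed": scenario.master_seed,
           "n": scenario.n,
           "parameter_digest": params.digest(),
           "package_version": __version__}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
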