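"""Proportional-hazards style risk engines and risk/hazard conversions.

All three engines (primary CVD, incident type 2 diabetes, recurrent CVD in
people with established disease) share the published functional form of
QRISK2-family scores:

    risk over horizon H = 1 - S0 ** exp(lp),   lp = sum_i w_i * x_i(ind)

where ``S0`` is the baseline survival at the horizon for a zero linear
predictor and the ``x_i`` are named covariate transforms. Coefficient sets
are data (CSV or in-config tables) so published coefficient sets can be
dropped in; the packaged defaults are illustrative, not the published
values.

The discrete-event engine consumes cumulative horizon risks through
:func:`risk_to_hazard`, which assumes a constant hazard over the horizon —
consistent with risks being refreshed at every event or every 10 years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError, DataError
from .population import Individual

# ---------------------------------------------------------------------------
# Covariate transforms
#
# Each engine coefficient names a transform; engines stay data-driven and a
# new transform is one registry entry. Continuous covariates are centred and
# scaled so weights of order 0.1-1 are sensible.

TRANSFORMS: dict[str, Callable[[Individual], float]] = {
    "one": lambda ind: 1.0,
    "age_centered": lambda ind: (ind.age - 60.0) / 10.0,
    "age_centered_sq": lambda ind: ((ind.age - 60.0) / 10.0) ** 2,
    "female": lambda ind: 1.0 if ind.sex == "female" else 0.0,
    "sbp_centered": lambda ind: (ind.sbp - 130.0) / 20.0,
    "chol_ratio_centered": lambda ind: ind.chol_ratio - 4.0,
    "bmi_centered": lambda ind: (ind.bmi - 27.0) / 5.0,
    "deprivation": lambda ind: ind.deprivation / 3.0,
    "smoker_ex": lambda ind: 1.0 if ind.smoking == "ex" else 0.0,
    "smoker_current": lambda ind: 1.0 if ind.smoking == "current" else 0.0,
    "ethnicity_south_asian": lambda ind: 1.0 if ind.ethnicity == "south_asian" else 0.0,
    "ethnicity_black": lambda ind: 1.0 if ind.ethnicity == "black" else 0.0,
    "ethnicity_other": lambda ind: 1.0 if ind.ethnicity == "other" else 0.0,
    "diabetes": lambda ind: 1.0 if ind.diabetes else 0.0,
    "family_history_chd": lambda ind: 1.0 if ind.family_history_chd else 0.0,
    "treated_hypertension": lambda ind: 1.0 if ind.treated_hypertension else 0.0,
    "age_sbp_interaction": lambda ind: (ind.age - 60.0) / 10.0 * (ind.sbp - 130.0) / 20.0,
    "n_prior_events": lambda ind: float(len(ind.cvd_history)),
    "prior_mi": lambda ind: 1.0 if any(e.type == "mi" for e in ind.cvd_history) else 0.0,
    "prior_stroke": lambda ind: 1.0 if any(e.type == "stroke" for e in ind.cvd_history) else 0.0,
}


@dataclass(frozen=True)
class Term:
    name: str        # label, e.g. "age"
    transform: str   # key into TRANSFORMS
    weight: float


@dataclass(frozen=True)
class RiskCoefficients:
    """One engine's coefficient set.

    ``baseline_survival`` is the survival probability at ``horizon`` years
    for an individual whose linear predictor is zero (i.e. at the centring
    point of every transform).
    """

    engine_name: str
    horizon: float                      # years
    baseline_survival: float            # in (0, 1]
    terms: tuple = field(default_factory=tuple)   # tuple[Term, ...]

    def validate(self) -> None:
        problems = []
        if self.horizon <= 0:
            problems.append(f"{self.engine_name}: horizon must be > 0")
        if not 0.0 < self.baseline_survival <= 1.0:
            problems.append(
                f"{self.engine_name}: baseline_survival must be in (0,1], "
                f"got {self.baseline_survival}")
        for t in self.terms:
            if t.transform not in TRANSFORMS:
                problems.append(
                    f"{self.engine_name}: unknown transform {t.transform!r} "
                    f"for term {t.name!r}")
        if problems:
            raise ConfigurationError("; ".join(problems))


@dataclass(frozen=True)
class RiskEstimate:
    probability: float   # cumulative event probability over the horizon
    horizon: float       # years


def linear_predictor(ind: Individual, coeffs: RiskCoefficients) -> float:
    lp = 0.0
    for t in coeffs.terms:
        try:
            lp += t.weight * TRANSFORMS[t.transform](ind)
        except KeyError:
            raise ConfigurationError(
                f"{coeffs.engine_name}: unknown transform {t.transform!r}")
        except (AttributeError, TypeError) as exc:
            raise DataError(
                f"individual id={getattr(ind, 'id', '?')} missing covariate "
                f"for term {t.name!r} of engine {coeffs.engine_name}: {exc}"
            ) from exc
    return lp


def _evaluate(ind: Individual, coeffs: RiskCoefficients) -> RiskEstimate:
    lp = linear_predictor(ind, coeffs)
    p = 1.0 - coeffs.baseline_survival ** math.exp(lp)
    return RiskEstimate(probability=min(max(p, 0.0), 1.0),
                        horizon=coeffs.horizon)


def primary_cvd_risk(ind: Individual, coeffs: RiskCoefficients) -> RiskEstimate:
    """First-event CVD risk (TIA/stroke/MI/angina composite) over the
    engine horizon (10 years under the default coefficient set)."""
    if ind.has_cvd:
        raise ContractError(
            f"primary_cvd_risk called for id={ind.id} with established CVD; "
            "use secondary_cvd_risk")
    return _evaluate(ind, coeffs)


def diabetes_risk(ind: Individual, coeffs: RiskCoefficients) -> RiskEstimate:
    """10-year risk of incident type 2 diabetes for a non-diabetic person."""
    if ind.diabetes:
        raise ContractError(
            f"diabetes_risk called for id={ind.id} who already has diabetes")
    return _evaluate(ind, coeffs)


def secondary_cvd_risk(ind: Individual, coeffs: RiskCoefficients) -> RiskEstimate:
    """Composite next-event risk for a person with established CVD
    (REACH-style recurrent-event engine; default horizon 5 years)."""
    if not ind.has_cvd:
        raise ContractError(
            f"secondary_cvd_risk called for id={ind.id} without established "
            "CVD; use primary_cvd_risk")
    return _evaluate(ind, coeffs)


def risk_to_hazard(est: RiskEstimate) -> float:
    """Constant yearly hazard reproducing the horizon risk:
    lambda = -ln(1 - p) / H."""
    if est.probability >= 1.0:
        raise ContractError("probability 1 implies an infinite hazard")
    if est.probability < 0.0:
        raise ContractError("probability must be >= 0")
    return -math.log1p(-est.probability) / est.horizon


def hazard_to_risk(hazard: float, horizon: float) -> float:
    """Inverse of :func:`risk_to_hazard`: p = 1 - exp(-lambda * H)."""
    if hazard < 0:
        raise ContractError("hazard must be >= 0")
    return -math.expm1(-hazard * horizon)


def sample_time_to_event(hazard: float, rng: np.random.Generator) -> float:
    """Exponential event time at the given yearly rate; rate 0 never fires.

    Always consumes exactly one draw from ``rng`` so call sequences stay
    aligned across scenarios compared under common random numbers.
    """
    if hazard < 0:
        raise ContractError(f"hazard must be >= 0, got {hazard}")
    e = rng.exponential()
    return e / hazard if hazard > 0 else math.inf


def five_year_risk(ind: Individual, coeffs: RiskCoefficients) -> float:
    """Convert the engine's horizon risk to 5 years under a constant hazard.

    Used as the default trial-inclusion engine: the historical entry
    criterion is a 5-year risk threshold while the primary engine predicts
    over 10 years; under a constant hazard
    ``p5 = 1 - (1 - pH)**(5/H)``.
    """
    est = primary_cvd_risk(ind, coeffs)
    return -math.expm1(math.log1p(-est.probability) * 5.0 / est.horizon)


# ---------------------------------------------------------------------------
# CSV interface: columns engine, term_name, transform, weight, plus one
# metadata row per engine (term_name "_meta") carrying horizon and baseline
# survival.

def coefficients_to_csv(coeff_sets: list[RiskCoefficients], path) -> None:
    rows = []
    for c in coeff_sets:
        rows.append({"engine": c.engine_name, "term_name": "_meta",
                     "transform": f"horizon={c.horizon};baseline_survival={c.baseline_survival}",
                     "weight": ""})
        for t in c.terms:
            rows.append({"engine": c.engine_name, "term_name": t.name,
                         "transform": t.transform, "weight": t.weight})
    pd.DataFrame(rows).to_csv(path, index=False)


def coefficients_from_csv(path) -> dict[str, RiskCoefficients]:
    df = pd.read_csv(path)
    engines: dict[str, RiskCoefficients] = {}
    for name, group in df.groupby("engine", sort=False):
        meta = group[group["term_name"] == "_meta"]
        if len(meta) != 1:
            raise ConfigurationError(
                f"engine {name!r}: expected exactly one _meta row, "
                f"found {len(meta)}")
        kv = dict(item.split("=") for item in str(meta.iloc[0]["transform"]).split(";"))
        terms = tuple(
            Term(str(r["term_name"]), str(r["transform"]), float(r["weight"]))
            for _, r in group[group["term_name"] != "_meta"].iterrows())
        coeffs = RiskCoefficients(
            engine_name=str(name),
            horizon=float(kv["horizon"]),
            baseline_survival=float(kv["baseline_survival"]),
            terms=terms)
        coeffs.validate()
        engines[str(name)] = coeffs
    return engines
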