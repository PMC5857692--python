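"""Medication adherence: endpoint definition, regression models, the
polypill adherence effect and treatment cessation.

Adherence uses the trial endpoint definition: self-reported use of a
statin, an antiplatelet and at least two blood-pressure-lowering agents on
at least 4 of the preceding 7 days (all three components simultaneously).

Under usual care the probability that a person is adherent comes from a
logistic regression on individual characteristics. In the polypill arm
that probability is multiplied by a relative risk of adherence (estimated
from a two-arm trial dataset with a log-link binomial regression) and
capped at 1. People may also stop medication altogether: cessation is a
constant-hazard process, after which treatment effects and drug costs no
longer apply.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ContractError, DataError, FittingError
from .population import Individual
from .risk import TRANSFORMS

#: minimum days per week, per component, for the endpoint to count as adherent
DAYS_THRESHOLD = 4
#: number of distinct blood-pressure-lowering agents required
MIN_ANTIHYPERTENSIVES = 2


def classify_adherent(statin_days: int, antiplatelet_days: int,
                      antihypertensive_days: Sequence[int]) -> bool:
    """Apply the trial adherence endpoint to one week of self-reported use.

    True iff the statin and the antiplatelet were each used on >= 4 days
    AND at least two antihypertensive agents were each used on >= 4 days.
    """
    counts = [statin_days, antiplatelet_days, *antihypertensive_days]
    for c in counts:
        if not 0 <= int(c) <= 7 or int(c) != c:
            raise DataError(f"day count must be an integer in 0..7, got {c!r}")
    n_aht_ok = sum(1 for d in antihypertensive_days if d >= DAYS_THRESHOLD)
    return (statin_days >= DAYS_THRESHOLD
            and antiplatelet_days >= DAYS_THRESHOLD
            and n_aht_ok >= MIN_ANTIHYPERTENSIVES)


@dataclass
class AdherenceModel:
    """Logistic model of the usual-care adherence probability.

    ``weights`` are keyed by covariate-transform names shared with the
    risk engines (see :data:`polypillsim.risk.TRANSFORMS`), so the same
    individual record feeds both. ``stderr`` holds the fitted standard
    errors when the model came from :func:`fit_adherence_model`.
    """

    intercept: float = 0.0
    weights: dict = field(default_factory=dict)        # transform name -> weight
    cessation_hazard: float = 0.05                     # per year, >= 0
    link: str = "logit"
    stderr: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.cessation_hazard < 0:
            raise ContractError("cessation_hazard must be >= 0")
        if self.link != "logit":
            raise ContractError(f"unsupported link {self.link!r}")
        for name in self.weights:
            if name not in TRANSFORMS:
                raise ContractError(f"unknown adherence covariate {name!r}")

    def linear_predictor(self, ind: Individual) -> float:
        lp = self.intercept
        for name, w in self.weights.items():
            lp += w * TRANSFORMS[name](ind)
        return lp


@dataclass
class AdherenceRR:
    """Relative risk of adherence, polypill vs usual care, with a CI."""

    rr: float = 1.0
    ci_low: float = 1.0
    ci_high: float = 1.0

    def validate(self) -> None:
        if not (self.ci_low > 0 and self.rr > 0 and self.ci_high > 0):
            raise ContractError("adherence RR and CI bounds must be > 0")
        if not self.ci_low <= self.rr <= self.ci_high:
            raise ContractError(
                f"CI must bracket the RR: {self.ci_low} <= {self.rr} "
                f"<= {self.ci_high} violated")


def _invlogit(x: float) -> float:
    # numerically stable
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def prob_adherent(ind: Individual, model: AdherenceModel, arm: str,
                  rr: AdherenceRR) -> float:
    """Per-period adherence probability for one person in one arm.

    Usual care ignores the RR entirely; the polypill arm multiplies the
    usual-care probability by ``rr.rr`` on the risk scale, capped at 1.
    """
    p = _invlogit(model.linear_predictor(ind))
    if arm == "polypill":
        return min(1.0, p * rr.rr)
    if arm == "usual":
        return p
    raise ContractError(f"unknown arm {arm!r}")


def fit_adherence_model(records: pd.DataFrame, predictors: Sequence[str],
                        cessation_hazard: float = 0.05) -> AdherenceModel:
    """Maximum-likelihood logistic fit of adherence on individual covariates.

    ``records`` needs an ``adherent`` 0/1 column plus one column per
    predictor, with columns already on the transform scale named in
    ``predictors`` (so the fitted weights plug straight into
    :meth:`AdherenceModel.linear_predictor`).
    """
    y = records["adherent"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise FittingError("adherence outcome has a single class; cannot fit")
    X = sm.add_constant(records[list(predictors)].to_numpy(dtype=float))
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    except Exception as exc:   # statsmodels raises several types here
        raise FittingError(f"adherence model failed to fit: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise FittingError(
            "adherence model fit is degenerate (separation?): "
            f"params={res.params}, se={res.bse}")
    names = ["const", *predictors]
    return AdherenceModel(
        intercept=float(res.params[0]),
        weights={n: float(w) for n, w in zip(predictors, res.params[1:])},
        cessation_hazard=cessation_hazard,
        stderr={n: float(s) for n, s in zip(names, res.bse)},
    )


def estimate_polypill_rr(trial: pd.DataFrame) -> AdherenceRR:
    """Log-link binomial regression of adherence on arm; exponentiated arm
    coefficient with a 95% Wald interval.

    ``trial`` needs columns ``arm`` ("usual"/"polypill") and ``adherent``
    (0/1). Both arms must contain adherent people (the log-RR is otherwise
    unidentified).
    """
    arms = set(trial["arm"])
    if not {"usual", "polypill"} <= arms:
        raise FittingError(f"both arms required, found {sorted(arms)}")
    y = trial["adherent"].to_numpy(dtype=float)
    z = (trial["arm"] == "polypill").to_numpy(dtype=float)
    p0 = y[z == 0].mean()
    p1 = y[z == 1].mean()
    if p0 == 0 or p1 == 0:
        raise FittingError("an arm has zero adherent participants; "
                           "log-binomial RR is undefined")
    X = sm.add_constant(z)
    start = np.array([math.log(p0), math.log(p1 / p0)])
    try:
        with warnings.catch_warnings():
            # statsmodels warns that the log link does not respect the
            # binomial domain; with an arm indicator the fit is saturated
            # and stays in-domain
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X,
                         family=sm.families.Binomial(sm.families.links.Log())
                         ).fit(start_params=start)
    except Exception as exc:
        raise FittingError(f"log-binomial RR fit failed: {exc}") from exc
    b, se = float(res.params[1]), float(res.bse[1])
    rr = AdherenceRR(rr=math.exp(b),
                     ci_low=math.exp(b - 1.959963984540054 * se),
                     ci_high=math.exp(b + 1.959963984540054 * se))
    rr.validate()
    return rr


def sample_cessation_time(model: AdherenceModel,
                          rng: np.random.Generator) -> float:
    """Years until the person stops medication; hazard 0 means never.

    Consumes exactly one exponential draw (common-random-number safe)."""
    if model.cessation_hazard < 0:
        raise ContractError("cessation_hazard must be >= 0")
    e = rng.exponential()
    return e / model.cessation_hazard if model.cessation_hazard > 0 else math.inf


# ---------------------------------------------------------------------------
# Synthetic two-arm trial generator (emulates the adherence endpoint of a
# fixed-dose combination trial; see docs/methods.md for what it does and
# does not reproduce)

TRIAL_PREDICTORS = ("age_centered", "female", "deprivation")


def simulate_adherence_trial(n_per_arm: int, model: AdherenceModel,
                             true_rr: float, seed: int) -> pd.DataFrame:
    """Two-arm adherence dataset drawn from a known generating process.

    Covariates: age ~ N(62, 10), sex ~ Bernoulli(0.5), deprivation score
    ~ N(0, 3). Usual-care adherence follows ``model``; the polypill arm
    multiplies the individual probability by ``true_rr`` (capped at 1).
    Columns: id, arm, adherent, plus the transform-scale predictors.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    age = rng.normal(62.0, 10.0, size=n)
    female = (rng.random(n) < 0.5).astype(float)
    deprivation = rng.normal(0.0, 3.0, size=n)
    arm = np.array(["usual"] * n_per_arm + ["polypill"] * n_per_arm)

    cols = {"age_centered": (age - 60.0) / 10.0,
            "female": female,
            "deprivation": deprivation / 3.0}
    lp = np.full(n, model.intercept)
    for name, w in model.weights.items():
        lp += w * cols[name]
    p = 1.0 / (1.0 + np.exp(-lp))
    p = np.where(arm == "polypill", np.minimum(1.0, p * true_rr), p)
    adherent = (rng.random(n) < p).astype(int)

    return pd.DataFrame({"id": np.arange(n), "arm": arm,
                         "adherent": adherent, **cols})
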