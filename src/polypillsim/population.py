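"""Synthetic cohort generation for a high-cardiovascular-risk population.

The model population mirrors the structure of a national cross-sectional
health survey (age, sex, ethnicity, smoking, systolic blood pressure,
total/HDL cholesterol ratio, BMI, area deprivation, diabetes status, prior
CVD events, current medication use) restricted to trial-style entry
criteria: adults with established atherothrombotic CVD or a 5-year CVD risk
at or above a threshold (default 15%).

No real survey records are used or emulated record-by-record: marginals are
parametric (:class:`PopulationSpec`), the joint distribution of the
continuous risk factors is a Gaussian copula with a configurable
correlation matrix, and everything is reproducible from a single seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

ETHNICITIES = ("white", "south_asian", "black", "other")
SMOKING_LEVELS = ("non", "ex", "current")
SEXES = ("female", "male")
#: prior-event types that mark established CVD at entry
PRIOR_EVENT_TYPES = ("mi", "stroke", "angina", "tia")

# continuous fields covered by the copula, in fixed order
_COPULA_FIELDS = ("age", "sbp", "chol_ratio", "bmi", "deprivation")


@dataclass
class MedicationProfile:
    """Current preventive-medication use for one person."""

    statin: bool = False
    n_antihypertensives: int = 0
    acei: bool = False
    aspirin: bool = False


@dataclass
class PriorEvent:
    """A CVD event that occurred before model entry."""

    type: str                  # one of PRIOR_EVENT_TYPES
    years_before_entry: float  # >= 0


@dataclass
class Individual:
    """One simulated person at model entry.

    ``cvd_history`` being non-empty is the definition of established CVD;
    the :meth:`has_cvd` property is the single source of truth for that
    flag throughout the package.
    """

    id: int
    age: float                      # years, >= 18 at entry
    sex: str                        # "female" | "male"
    ethnicity: str                  # one of ETHNICITIES
    smoking: str                    # "non" | "ex" | "current"
    sbp: float                      # systolic blood pressure, mmHg
    chol_ratio: float               # total / HDL cholesterol (dimensionless)
    bmi: float                      # kg/m^2
    deprivation: float              # Townsend-style score (higher = more deprived)
    diabetes: bool = False
    family_history_chd: bool = False
    treated_hypertension: bool = False
    cvd_history: list = field(default_factory=list)   # list[PriorEvent]
    meds: MedicationProfile = field(default_factory=MedicationProfile)

    @property
    def has_cvd(self) -> bool:
        return len(self.cvd_history) > 0

    def validate(self) -> None:
        problems = []
        if self.age < 18:
            problems.append(f"id={self.id}: age {self.age} < 18")
        if self.sbp <= 0:
            problems.append(f"id={self.id}: sbp must be > 0")
        if self.chol_ratio <= 0:
            problems.append(f"id={self.id}: chol_ratio must be > 0")
        if self.bmi <= 0:
            problems.append(f"id={self.id}: bmi must be > 0")
        if self.meds.n_antihypertensives < 0:
            problems.append(f"id={self.id}: n_antihypertensives must be >= 0")
        if self.sex not in SEXES:
            problems.append(f"id={self.id}: unknown sex {self.sex!r}")
        if self.smoking not in SMOKING_LEVELS:
            problems.append(f"id={self.id}: unknown smoking {self.smoking!r}")
        if self.ethnicity not in ETHNICITIES:
            problems.append(f"id={self.id}: unknown ethnicity {self.ethnicity!r}")
        if problems:
            raise DataError("; ".join(problems))


@dataclass
class PopulationSpec:
    """Marginal distributions, correlation structure and prevalences.

    Continuous fields are normal marginals (clipped to physiological
    ranges); categorical fields are independent draws at the stated
    prevalences. Defaults describe a secondary/high-primary-risk adult
    population of the kind recruited into fixed-dose combination trials.
    """

    n: int = 1000
    seed: int = 0

    age_mean: float = 62.0
    age_sd: float = 12.0
    sbp_mean: float = 140.0
    sbp_sd: float = 18.0
    chol_ratio_mean: float = 4.2
    chol_ratio_sd: float = 1.0
    bmi_mean: float = 28.0
    bmi_sd: float = 4.5
    deprivation_mean: float = 0.0
    deprivation_sd: float = 3.0

    p_female: float = 0.45
    smoking_probs: tuple = (0.55, 0.25, 0.20)          # non, ex, current
    ethnicity_probs: tuple = (0.82, 0.08, 0.04, 0.06)  # matches ETHNICITIES
    p_diabetes: float = 0.10
    p_family_history: float = 0.15
    p_treated_hypertension: float = 0.40
    p_cvd: float = 0.25

    p_statin: float = 0.55
    p_aspirin: float = 0.45
    p_acei: float = 0.30
    n_aht_probs: tuple = (0.35, 0.30, 0.25, 0.10)      # P(0), P(1), P(2), P(3)

    #: pairwise correlations among continuous fields (Gaussian copula);
    #: keys are frozensets understood as unordered pairs of field names
    correlations: dict = field(default_factory=lambda: {
        ("age", "sbp"): 0.35,
        ("age", "bmi"): 0.10,
    })

    def validate(self) -> None:
        problems = []
        if self.n < 1:
            problems.append(f"n must be >= 1, got {self.n}")
        for name in ("age_sd", "sbp_sd", "chol_ratio_sd", "bmi_sd",
                     "deprivation_sd"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        for name in ("p_female", "p_diabetes", "p_family_history",
                     "p_treated_hypertension", "p_cvd", "p_statin",
                     "p_aspirin", "p_acei"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name} must be in [0,1], got {v}")
        for name, probs, k in (("smoking_probs", self.smoking_probs, 3),
                               ("ethnicity_probs", self.ethnicity_probs, 4),
                               ("n_aht_probs", self.n_aht_probs, 4)):
            if len(probs) != k or any(p < 0 for p in probs) or \
                    abs(sum(probs) - 1.0) > 1e-9:
                problems.append(f"{name} must be {k} non-negative values summing to 1")
        try:
            np.linalg.cholesky(self.correlation_matrix())
        except np.linalg.LinAlgError:
            problems.append("correlations do not form a positive-definite matrix")
        if problems:
            raise ConfigurationError("invalid PopulationSpec: " + "; ".join(problems))

    def correlation_matrix(self) -> np.ndarray:
        m = np.eye(len(_COPULA_FIELDS))
        idx = {f: i for i, f in enumerate(_COPULA_FIELDS)}
        for pair, rho in self.correlations.items():
            a, b = pair
            if a not in idx or b not in idx:
                raise ConfigurationError(
                    f"correlation names unknown field in pair {pair!r}")
            m[idx[a], idx[b]] = m[idx[b], idx[a]] = rho
        return m


def generate_population(spec: PopulationSpec) -> list[Individual]:
    """Draw ``spec.n`` individuals; byte-identical output for equal seeds.

    Continuous risk factors come from a Gaussian copula with the spec's
    correlation matrix and normal marginals, clipped to plausible ranges
    (age to [18, 99] so the adult-entry invariant holds by construction).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    chol = np.linalg.cholesky(spec.correlation_matrix())
    z = rng.standard_normal((n, len(_COPULA_FIELDS))) @ chol.T

    means = [spec.age_mean, spec.sbp_mean, spec.chol_ratio_mean,
             spec.bmi_mean, spec.deprivation_mean]
    sds = [spec.age_sd, spec.sbp_sd, spec.chol_ratio_sd,
           spec.bmi_sd, spec.deprivation_sd]
    x = z * np.asarray(sds) + np.asarray(means)

    age = np.clip(x[:, 0], 18.0, 99.0)
    sbp = np.clip(x[:, 1], 70.0, 250.0)
    chol_ratio = np.clip(x[:, 2], 1.5, 12.0)
    bmi = np.clip(x[:, 3], 15.0, 60.0)
    deprivation = x[:, 4]

    female = rng.random(n) < spec.p_female
    smoking = rng.choice(len(SMOKING_LEVELS), size=n, p=spec.smoking_probs)
    ethnicity = rng.choice(len(ETHNICITIES), size=n, p=spec.ethnicity_probs)
    diabetes = rng.random(n) < spec.p_diabetes
    fam = rng.random(n) < spec.p_family_history
    treated_ht = rng.random(n) < spec.p_treated_hypertension
    has_cvd = rng.random(n) < spec.p_cvd
    statin = rng.random(n) < spec.p_statin
    aspirin = rng.random(n) < spec.p_aspirin
    acei = rng.random(n) < spec.p_acei
    n_aht = rng.choice(len(spec.n_aht_probs), size=n, p=spec.n_aht_probs)

    people = []
    for i in range(n):
        history: list[PriorEvent] = []
        if has_cvd[i]:
            n_events = 1 + int(rng.random() < 0.3)
            for _ in range(n_events):
                etype = PRIOR_EVENT_TYPES[rng.choice(len(PRIOR_EVENT_TYPES))]
                history.append(PriorEvent(etype, float(rng.uniform(0.0, 10.0))))
        people.append(Individual(
            id=i,
            age=float(age[i]),
            sex="female" if female[i] else "male",
            ethnicity=ETHNICITIES[ethnicity[i]],
            smoking=SMOKING_LEVELS[smoking[i]],
            sbp=float(sbp[i]),
            chol_ratio=float(chol_ratio[i]),
            bmi=float(bmi[i]),
            deprivation=float(deprivation[i]),
            diabetes=bool(diabetes[i]),
            family_history_chd=bool(fam[i]),
            treated_hypertension=bool(treated_ht[i]),
            cvd_history=history,
            meds=MedicationProfile(
                statin=bool(statin[i]),
                n_antihypertensives=int(n_aht[i]),
                acei=bool(acei[i]),
                aspirin=bool(aspirin[i]),
            ),
        ))
    return people


def apply_inclusion(pop: Iterable[Individual],
                    inclusion_engine: Callable[[Individual], float],
                    threshold: float = 0.15) -> list[Individual]:
    """Filter to the modelled entry criteria, preserving order.

    Retains adults (age >= 18) who either have established CVD or whose
    5-year CVD risk from ``inclusion_engine`` is at or above ``threshold``
    (default 15%). Idempotent by construction. ``inclusion_engine`` takes
    an :class:`Individual` without established CVD and returns a 5-year
    cumulative risk in [0, 1].
    """
    kept = []
    for ind in pop:
        if ind.age < 18:
            continue
        if ind.has_cvd:
            kept.append(ind)
            continue
        try:
            risk = inclusion_engine(ind)
        except DataError:
            raise
        except (AttributeError, TypeError, KeyError) as exc:
            raise DataError(
                f"individual id={ind.id} missing a covariate required "
                f"by the inclusion engine: {exc}") from exc
        if risk >= threshold:
            kept.append(ind)
    return kept


def build_cohort(n: int, spec: PopulationSpec,
                 inclusion_engine: Callable[[Individual], float],
                 threshold: float = 0.15,
                 max_batches: int = 200) -> list[Individual]:
    """Generate candidates in batches until ``n`` pass the entry criteria.

    Convenience wrapper around :func:`generate_population` +
    :func:`apply_inclusion`; ids are re-assigned 0..n-1 so downstream
    RNG substreams are dense.
    """
    kept: list[Individual] = []
    batch = dataclasses.replace(spec, n=max(n, 100))
    for b in range(max_batches):
        batch = dataclasses.replace(batch, seed=spec.seed + b)
        kept.extend(apply_inclusion(generate_population(batch),
                                    inclusion_engine, threshold))
        if len(kept) >= n:
            break
    else:
        raise ConfigurationError(
            f"could not assemble {n} eligible individuals in "
            f"{max_batches} batches; inclusion threshold too strict "
            f"for this population spec")
    kept = kept[:n]
    for i, ind in enumerate(kept):
        ind.id = i
    return kept


# ---------------------------------------------------------------------------
# CSV round trip

_BOOL_COLS = ("diabetes", "family_history_chd", "treated_hypertension",
              "statin", "acei", "aspirin")


def population_to_csv(pop: Sequence[Individual], path) -> None:
    """One individual per row; prior events as ``type:years`` tokens
    joined by semicolons."""
    rows = []
    for ind in pop:
        rows.append({
            "id": ind.id, "age": ind.age, "sex": ind.sex,
            "ethnicity": ind.ethnicity, "smoking": ind.smoking,
            "sbp": ind.sbp, "chol_ratio": ind.chol_ratio, "bmi": ind.bmi,
            "deprivation": ind.deprivation,
            "diabetes": int(ind.diabetes),
            "family_history_chd": int(ind.family_history_chd),
            "treated_hypertension": int(ind.treated_hypertension),
            "statin": int(ind.meds.statin),
            "n_antihypertensives": ind.meds.n_antihypertensives,
            "acei": int(ind.meds.acei),
            "aspirin": int(ind.meds.aspirin),
            "cvd_history": ";".join(
                f"{e.type}:{e.years_before_entry!r}" for e in ind.cvd_history),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def population_from_csv(path) -> list[Individual]:
    df = pd.read_csv(path, keep_default_na=False,
                     float_precision="round_trip")
    people = []
    for _, row in df.iterrows():
        history = []
        raw = str(row["cvd_history"])
        if raw:
            for token in raw.split(";"):
                try:
                    etype, years = token.split(":")
                    history.append(PriorEvent(etype, float(years)))
                except ValueError as exc:
                    raise DataError(
                        f"id={row['id']}: malformed cvd_history token "
                        f"{token!r}") from exc
        people.append(Individual(
            id=int(row["id"]), age=float(row["age"]), sex=str(row["sex"]),
            ethnicity=str(row["ethnicity"]), smoking=str(row["smoking"]),
            sbp=float(row["sbp"]), chol_ratio=float(row["chol_ratio"]),
            bmi=float(row["bmi"]), deprivation=float(row["deprivation"]),
            diabetes=bool(int(row["diabetes"])),
            family_history_chd=bool(int(row["family_history_chd"])),
            treated_hypertension=bool(int(row["treated_hypertension"])),
            cvd_history=history,
            meds=MedicationProfile(
                statin=bool(int(row["statin"])),
                n_antihypertensives=int(row["n_antihypertensives"]),
                acei=bool(int(row["acei"])),
                aspirin=bool(int(row["aspirin"])),
            ),
        ))
    return people
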