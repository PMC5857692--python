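"""Discrete-event simulation core.

Each person is driven through a lifetime event history by competing
exponential clocks under piecewise-constant hazards. At every state point
(entry, any event, or the scheduled 10-year risk refresh) the engine:

1. recomputes all cause-specific hazards from the risk engines and current
   state (primary CVD engine before the first CVD event, the recurrent-event
   engine after; diabetes clock only while non-diabetic; heart failure at
   the age-interpolated incidence; GI bleeding; constant cessation hazard
   while on treatment; other-cause mortality from the life table),
2. samples one clock per cause and fires the earliest, unless the
   deterministic risk-update or the age cap comes first,
3. resolves the fired event (CVD type split, acute case fatality, state
   update) and repeats until death or age 100.

Resampling all clocks at every state point is statistically equivalent to
carrying unexpired clocks forward because exponential clocks are
memoryless; it keeps the implementation simple and the random-number
consumption per state point constant, which is what makes common random
numbers across scenario arms exact (identical draw sequences whenever the
state sequences coincide).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .adherence import prob_adherent
from .effects import adjusted_cvd_hazard, adverse_event_hazards, heart_failure_hazard
from .errors import ConfigurationError, ContractError
from .mortality import CaseFatality, LifeTable
from .population import Individual, MedicationProfile, PriorEvent
from .risk import (RiskEstimate, diabetes_risk, primary_cvd_risk,
                   risk_to_hazard, secondary_cvd_risk)


class EventType(str, Enum):
    TIA = "tia"
    STROKE = "stroke"
    MI = "mi"
    ANGINA = "angina"
    DIABETES_ONSET = "diabetes_onset"
    GI_BLEED = "gi_bleed"
    COUGH_ONSET = "cough_onset"
    HEART_FAILURE = "heart_failure"
    CESSATION = "cessation"
    RISK_UPDATE = "risk_update"
    OTHER_CAUSE_DEATH = "other_cause_death"
    CVD_DEATH = "cvd_death"


#: acute CVD event types, in the fixed order of the relative-incidence vector
CVD_EVENT_TYPES = (EventType.TIA, EventType.STROKE, EventType.MI,
                   EventType.ANGINA)


@dataclass
class EventRecord:
    time: float          # years from entry
    type: EventType
    fatal: bool = False
    age: float = 0.0     # age at event


@dataclass
class ExposureInterval:
    start: float
    end: float
    on_treatment: bool
    adherent: bool


@dataclass
class Trajectory:
    """Time-ordered record of one person's simulated lifetime in one arm."""

    individual_id: int
    arm: str
    entry_age: float
    sex: str
    events: list = field(default_factory=list)      # list[EventRecord]
    exposure: list = field(default_factory=list)    # list[ExposureInterval]
    exit_reason: str = ""                           # "death" | "age_cap"
    exit_time: float = 0.0

    @property
    def exit_age(self) -> float:
        return self.entry_age + self.exit_time

    def count(self, *types: EventType) -> int:
        wanted = set(types)
        return sum(1 for e in self.events if e.type in wanted)

    def n_cvd_events(self) -> int:
        return self.count(*CVD_EVENT_TYPES)


def split_cvd_event(rel_incidence: Sequence[float],
                    rng: np.random.Generator) -> EventType:
    """Categorical draw over (TIA, stroke, MI, angina)."""
    p = np.asarray(rel_incidence, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ContractError(
            "relative incidence must be 4 non-negative probabilities "
            f"summing to 1, got {rel_incidence!r}")
    u = rng.random()
    c = 0.0
    for prob, etype in zip(p, CVD_EVENT_TYPES):
        c += prob
        if u < c:
            return etype
    return CVD_EVENT_TYPES[-1]


def apply_case_fatality(event: EventType, age: float, cf: CaseFatality,
                        rng: np.random.Generator) -> bool:
    """Bernoulli fatality draw for an acute stroke or MI."""
    if event not in (EventType.STROKE, EventType.MI):
        raise ContractError(f"case fatality applies to stroke/MI, got {event}")
    return rng.random() < cf.probability(event.value, age)


def other_cause_death_time(age: float, sex: str, life_table: LifeTable,
                           rng: np.random.Generator) -> float:
    """Years until non-CVD death, from the life-table piecewise-exponential
    survival conditioned on being alive at ``age``."""
    return life_table.sample_death_time(age, sex, rng)


#: full indicated regimen: statin + antiplatelet + two BP-lowering agents
#: (one an ACE inhibitor), the composition a combination pill replicates
FULL_REGIMEN = MedicationProfile(statin=True, n_antihypertensives=2,
                                 acei=True, aspirin=True)

# fixed clock order within each state point (determines RNG draw order)
_CLOCKS = ("cvd", "diabetes", "gi_bleed", "heart_failure", "cessation",
           "other_death")

_CHECK_ATTRS = ("primary_coeffs", "secondary_coeffs", "diabetes_coeffs",
                "hf_baseline", "rel_incidence", "treatment_effects",
                "adherence_model", "adherence_rr", "case_fatality",
                "life_table", "baseline_gi_hazard")


def simulate_individual(ind: Individual, scenario, params,
                        rng: np.random.Generator) -> Trajectory:
    """Simulate one person's lifetime under one scenario arm.

    ``scenario`` needs ``arm`` ("usual" | "polypill"); ``params`` is a
    :class:`polypillsim.config.ParameterSet` (duck-typed). The input
    individual is never mutated: ageing, incident diabetes and the growing
    event history live on an internal copy.

    Both arms carry the same indicated regimen (the drug classes the
    combination pill contains); arms differ through the adherence
    probability, so under common random numbers and null effect sizes the
    two arms produce identical trajectories.
    """
    for attr in _CHECK_ATTRS:
        if getattr(params, attr, None) is None:
            raise ConfigurationError(
                f"parameter set is missing {attr!r}; cannot simulate")

    arm = scenario.arm
    if arm not in ("usual", "polypill"):
        raise ContractError(f"unknown arm {arm!r}")
    age_cap = float(params.age_cap)
    update_interval = float(params.risk_update_interval)
    fx = params.treatment_effects
    rel_inc = [params.rel_incidence[t.value] for t in CVD_EVENT_TYPES]

    traj = Trajectory(individual_id=ind.id, arm=arm, entry_age=ind.age,
                      sex=ind.sex)
    if ind.age >= age_cap:
        traj.exit_reason = "age_cap"
        traj.exit_time = 0.0
        return traj

    # mutable simulation state (the input record stays untouched)
    state = dataclasses.replace(ind, cvd_history=list(ind.cvd_history))
    meds = FULL_REGIMEN
    on_treatment = True
    had_hf = False
    coughed = False
    t = 0.0
    seg_start = 0.0

    def draw_adherent() -> bool:
        if not on_treatment:
            return False
        p = prob_adherent(state, params.adherence_model, arm,
                          params.adherence_rr)
        return rng.random() < p

    def _safe_hazard(est: RiskEstimate) -> float:
        # extreme covariate profiles can push the engine risk to 1.0 in
        # floating point; cap just below so the hazard stays finite
        if est.probability >= 1.0:
            est = RiskEstimate(1.0 - 1e-12, est.horizon)
        return risk_to_hazard(est)

    adherent = draw_adherent()

    # one-shot ACE-inhibitor cough at treatment initiation; the draw is
    # skipped entirely when the probability is zero so RNG sequences stay
    # aligned in null-scenario comparisons
    if (adherent and meds.acei and fx.p_cough_acei > 0.0
            and rng.random() < fx.p_cough_acei):
        traj.events.append(EventRecord(0.0, EventType.COUGH_ONSET, False,
                                       state.age))
        coughed = True

    def close_segment(end: float) -> None:
        nonlocal seg_start
        if end > seg_start:
            traj.exposure.append(ExposureInterval(seg_start, end,
                                                  on_treatment, adherent))
        seg_start = end

    next_update = update_interval

    while True:
        # --- cause-specific hazards at the current state point -----------
        if state.has_cvd:
            cvd_base = _safe_hazard(secondary_cvd_risk(
                state, params.secondary_coeffs))
        else:
            cvd_base = _safe_hazard(primary_cvd_risk(
                state, params.primary_coeffs))
        h_cvd = adjusted_cvd_hazard(cvd_base, meds, adherent, fx)

        if state.diabetes:
            dm_base = 0.0
        else:
            dm_base = _safe_hazard(diabetes_risk(state,
                                                 params.diabetes_coeffs))
        adverse = adverse_event_hazards(meds, adherent, dm_base,
                                        params.baseline_gi_hazard, fx)
        h_dm = adverse["diabetes"]
        h_gi = adverse["gi_bleed"]
        h_hf = 0.0 if had_hf else heart_failure_hazard(
            state.age, params.hf_baseline,
            adherent and meds.n_antihypertensives >= 1, fx)
        h_cess = params.adherence_model.cessation_hazard if on_treatment else 0.0

        # --- one clock per cause, fixed draw order ------------------------
        times = {}
        for cause, h in (("cvd", h_cvd), ("diabetes", h_dm),
                         ("gi_bleed", h_gi), ("heart_failure", h_hf),
                         ("cessation", h_cess)):
            e = rng.exponential()
            times[cause] = e / h if h > 0.0 else math.inf
        times["other_death"] = params.life_table.sample_death_time(
            state.age, state.sex, rng)

        cause = min(_CLOCKS, key=times.__getitem__)
        dt = times[cause]
        dt_update = next_update - t
        dt_cap = age_cap - state.age

        if dt_cap <= min(dt, dt_update):
            # age cap reached before anything else fires
            t += dt_cap
            state.age += dt_cap
            close_segment(t)
            traj.exit_reason = "age_cap"
            traj.exit_time = t
            return traj

        if dt_update <= dt:
            # scheduled risk refresh: recompute risks next loop, re-draw
            # adherence status for the new risk period
            t += dt_update
            state.age += dt_update
            close_segment(t)
            traj.events.append(EventRecord(t, EventType.RISK_UPDATE, False,
                                           state.age))
            adherent = draw_adherent()
            next_update = t + update_interval
            continue

        # a stochastic clock fires
        t += dt
        state.age += dt

        if cause == "other_death":
            close_segment(t)
            traj.events.append(EventRecord(t, EventType.OTHER_CAUSE_DEATH,
                                           True, state.age))
            traj.exit_reason = "death"
            traj.exit_time = t
            return traj

        if cause == "cessation":
            close_segment(t)
            traj.events.append(EventRecord(t, EventType.CESSATION, False,
                                           state.age))
            on_treatment = False
            adherent = False
            # stopping medication is a state change, not a clinical event:
            # risks refresh on the next loop, schedule stays
            continue

        if cause == "cvd":
            etype = split_cvd_event(rel_inc, rng)
            fatal = False
            if etype in (EventType.STROKE, EventType.MI):
                fatal = apply_case_fatality(etype, state.age,
                                            params.case_fatality, rng)
            traj.events.append(EventRecord(t, etype, fatal, state.age))
            if fatal:
                window = params.case_fatality.window(etype.value)
                death_t = t + window
                if state.age + window >= age_cap:
                    death_t = t + (age_cap - state.age)
                    close_segment(death_t)
                    traj.exit_reason = "age_cap"
                    traj.exit_time = death_t
                    return traj
                close_segment(death_t)
                traj.events.append(EventRecord(
                    death_t, EventType.CVD_DEATH, True,
                    state.age + window))
                traj.exit_reason = "death"
                traj.exit_time = death_t
                return traj
            # survivor: history grows, the recurrent-event engine takes over
            state.cvd_history.append(PriorEvent(etype.value, 0.0))
        elif cause == "diabetes":
            traj.events.append(EventRecord(t, EventType.DIABETES_ONSET,
                                           False, state.age))
            state.diabetes = True
        elif cause == "gi_bleed":
            traj.events.append(EventRecord(t, EventType.GI_BLEED, False,
                                           state.age))
        elif cause == "heart_failure":
            traj.events.append(EventRecord(t, EventType.HEART_FAILURE,
                                           False, state.age))
            had_hf = True

        # any clinical event is an update point: characteristics refresh
        # and the 10-year clock restarts
        close_segment(t)
        adherent = draw_adherent()
        next_update = t + update_interval
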