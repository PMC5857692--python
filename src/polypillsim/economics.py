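"""Costs and QALYs along a simulated trajectory, discounted in continuous
time.

A discrete-event model has no cycles, so discounting uses the continuous
analogue of the standard annual rate r (default 3.5%/year):

* a point cost c at time t contributes  c * (1+r)^(-t);
* a flow of c per year over [a, b] contributes
  c * ((1+r)^(-a) - (1+r)^(-b)) / ln(1+r)   (c*(b-a) when r = 0).

Cost accrual: acute event costs at exact event times; a one-off stopping
cost at medication cessation; yearly flows for drugs (while on treatment
and adherent), monitoring (while on treatment) and chronic post-event
states (from the first event of each type, for life).

QALY accrual: utility is baseline(age, sex) minus the sum of active
decrements, floored at 0. Chronic decrements start at the first event of
the type and persist; GI bleeding and cough carry transient decrements
with finite durations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .engine import EventType, Trajectory
from .errors import ConfigurationError, ContractError

#: chronic states triggered by events (state costs + utility decrements
#: persist from the first such event)
CHRONIC_STATES = {
    EventType.STROKE: "stroke",
    EventType.TIA: "tia",
    EventType.MI: "mi",
    EventType.ANGINA: "angina",
    EventType.DIABETES_ONSET: "diabetes",
    EventType.HEART_FAILURE: "heart_failure",
}

#: transient states: event -> state name in UtilityTable.transient
TRANSIENT_STATES = {
    EventType.GI_BLEED: "gi_bleed",
    EventType.COUGH_ONSET: "cough",
}


@dataclass
class CostTable:
    """All unit costs in pounds sterling (price year in ``currency_year``)."""

    acute: dict = field(default_factory=lambda: {
        "tia": 2000.0, "stroke": 10000.0, "mi": 5000.0, "angina": 3000.0,
        "diabetes_onset": 500.0, "gi_bleed": 2500.0, "cough_onset": 100.0,
        "heart_failure": 4000.0,
    })
    annual_state: dict = field(default_factory=lambda: {
        "stroke": 2500.0, "tia": 200.0, "mi": 500.0, "angina": 800.0,
        "diabetes": 1500.0, "heart_failure": 2000.0,
    })
    #: yearly drug costs per class; the regimen is statin + aspirin +
    #: ACE inhibitor + one further antihypertensive
    annual_med: dict = field(default_factory=lambda: {
        "statin": 20.0, "aspirin": 8.0, "acei": 15.0, "aht": 25.0,
    })
    polypill_annual: float | None = None   # None -> aggregate of components
    monitoring_annual: float = 50.0
    stopping_cost: float = 80.0            # e.g. two GP visits plus tests
    currency_year: int = 2015

    def validate(self) -> None:
        problems = []
        for group in (self.acute, self.annual_state, self.annual_med):
            for k, v in group.items():
                if v < 0:
                    problems.append(f"cost {k!r} must be >= 0, got {v}")
        for name in ("monitoring_annual", "stopping_cost"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.polypill_annual is not None and self.polypill_annual < 0:
            problems.append("polypill_annual must be >= 0")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def usual_med_annual(self) -> float:
        m = self.annual_med
        return m["statin"] + m["aspirin"] + m["acei"] + m["aht"]

    def polypill_cost(self) -> float:
        if self.polypill_annual is not None:
            return self.polypill_annual
        return polypill_annual_cost(list(self.annual_med.values()))


def polypill_annual_cost(component_costs, override: float | None = None) -> float:
    """Combination-pill yearly price: the aggregate of its component drug
    prices, unless a sensitivity price override is set."""
    if override is not None:
        if override < 0:
            raise ContractError("polypill price override must be >= 0")
        return float(override)
    costs = [float(c) for c in component_costs]
    if any(c < 0 for c in costs):
        raise ContractError("component costs must be >= 0")
    return sum(costs)


@dataclass
class UtilityTable:
    """EQ-5D-style utilities: age/sex baseline bands plus decrements."""

    #: sex -> tuple of (age_from, utility), piecewise-constant, ascending
    baseline: dict = field(default_factory=lambda: {
        "female": ((18.0, 0.92), (45.0, 0.86), (55.0, 0.82), (65.0, 0.79),
                   (75.0, 0.74), (85.0, 0.69)),
        "male": ((18.0, 0.91), (45.0, 0.85), (55.0, 0.81), (65.0, 0.78),
                 (75.0, 0.73), (85.0, 0.68)),
    })
    decrements: dict = field(default_factory=lambda: {
        "stroke": 0.15, "tia": 0.05, "mi": 0.08, "angina": 0.09,
        "diabetes": 0.07, "heart_failure": 0.15,
    })
    #: state -> (decrement, duration in years)
    transient: dict = field(default_factory=lambda: {
        "gi_bleed": (0.10, 0.25), "cough": (0.02, 1.0),
    })

    def validate(self) -> None:
        problems = []
        for sex, bands in self.baseline.items():
            ages = [a for a, _ in bands]
            if ages != sorted(ages) or len(ages) != len(set(ages)):
                problems.append(f"baseline bands for {sex!r} must have "
                                "strictly increasing ages")
            for a, u in bands:
                if not 0.0 <= u <= 1.0:
                    problems.append(
                        f"baseline utility {u} at age {a} ({sex}) outside [0,1]")
        for k, d in self.decrements.items():
            if d < 0:
                problems.append(f"decrement {k!r} must be >= 0")
        for k, (d, dur) in self.transient.items():
            if d < 0 or dur < 0:
                problems.append(f"transient {k!r} needs decrement and "
                                "duration >= 0")
        if problems:
            raise ConfigurationError("; ".join(problems))

    def baseline_at(self, age: float, sex: str) -> float:
        try:
            bands = self.baseline[sex]
        except KeyError:
            raise ConfigurationError(f"no baseline utilities for sex {sex!r}")
        if age < bands[0][0]:
            raise ConfigurationError(
                f"age {age} below first utility band ({bands[0][0]})")
        u = bands[0][1]
        for a, util in bands:
            if age >= a:
                u = util
            else:
                break
        return u


@dataclass
class DiscountedOutcome:
    cost: float
    qalys: float
    cost_undiscounted: float
    qalys_undiscounted: float


# ---------------------------------------------------------------------------
# discounting primitives

def present_value(amount: float, t: float, rate: float) -> float:
    if t < 0:
        raise ContractError(f"negative time {t}")
    return amount * (1.0 + rate) ** (-t)


def flow_present_value(per_year: float, start: float, end: float,
                       rate: float) -> float:
    """Integral of per_year * (1+rate)^(-t) dt over [start, end]."""
    if start < 0 or end < start:
        raise ContractError(f"bad flow interval [{start}, {end}]")
    if rate == 0.0:
        return per_year * (end - start)
    rho = math.log(1.0 + rate)
    return per_year * ((1.0 + rate) ** (-start) - (1.0 + rate) ** (-end)) / rho


def accrue_costs(traj: Trajectory, costs: CostTable, rate: float) -> float:
    """Discounted lifetime cost of one trajectory (see module docstring
    for what accrues when)."""
    if rate < 0:
        raise ContractError("discount rate must be >= 0")
    total = 0.0

    for ev in traj.events:
        if ev.time < 0:
            raise ContractError(f"negative event time {ev.time}")
        if ev.type == EventType.CESSATION:
            total += present_value(costs.stopping_cost, ev.time, rate)
        else:
            acute = costs.acute.get(ev.type.value)
            if acute:
                total += present_value(acute, ev.time, rate)

    # chronic state flows from the first event of each type to exit
    first_times: dict[str, float] = {}
    for ev in traj.events:
        st = CHRONIC_STATES.get(ev.type)
        if st is not None and st not in first_times:
            first_times[st] = ev.time
    for st, t0 in first_times.items():
        per_year = costs.annual_state.get(st, 0.0)
        if per_year and traj.exit_time > t0:
            total += flow_present_value(per_year, t0, traj.exit_time, rate)

    # medication + monitoring flows
    med_per_year = (costs.polypill_cost() if traj.arm == "polypill"
                    else costs.usual_med_annual())
    for seg in traj.exposure:
        if seg.on_treatment:
            total += flow_present_value(costs.monitoring_annual,
                                        seg.start, seg.end, rate)
            if seg.adherent:
                total += flow_present_value(med_per_year, seg.start,
                                            seg.end, rate)
    return total


def accrue_qalys(traj: Trajectory, utils: UtilityTable, rate: float) -> float:
    """Discounted QALYs: piecewise-constant utility integrated against the
    discount factor, with breakpoints at events, decrement expiries and
    age-band crossings."""
    if rate < 0:
        raise ContractError("discount rate must be >= 0")
    exit_t = traj.exit_time
    if exit_t <= 0:
        return 0.0

    # times at which active decrements change
    chronic_starts: list[tuple[float, float]] = []   # (time, decrement)
    transient_windows: list[tuple[float, float, float]] = []  # (t0, t1, d)
    seen: set[str] = set()
    for ev in traj.events:
        st = CHRONIC_STATES.get(ev.type)
        if st is not None and st not in seen:
            seen.add(st)
            chronic_starts.append((ev.time, utils.decrements.get(st, 0.0)))
        tr = TRANSIENT_STATES.get(ev.type)
        if tr is not None and tr in utils.transient:
            d, dur = utils.transient[tr]
            transient_windows.append((ev.time, ev.time + dur, d))

    breaks = {0.0, exit_t}
    breaks.update(t for t, _ in chronic_starts if t < exit_t)
    for t0, t1, _ in transient_windows:
        if t0 < exit_t:
            breaks.add(t0)
        if t1 < exit_t:
            breaks.add(t1)
    # age-band boundary crossings
    bands = utils.baseline.get(traj.sex)
    if bands is None:
        raise ConfigurationError(f"no baseline utilities for sex {traj.sex!r}")
    for a, _ in bands:
        t_cross = a - traj.entry_age
        if 0.0 < t_cross < exit_t:
            breaks.add(t_cross)

    points = sorted(breaks)
    total = 0.0
    for a, b in zip(points, points[1:]):
        mid = 0.5 * (a + b)
        u = utils.baseline_at(traj.entry_age + mid, traj.sex)
        u -= sum(d for t, d in chronic_starts if t <= mid)
        u -= sum(d for t0, t1, d in transient_windows if t0 <= mid < t1)
        u = max(u, 0.0)
        if u > 0.0:
            total += flow_present_value(u, a, b, rate)
    return total


def discounted_outcome(traj: Trajectory, costs: CostTable,
                       utils: UtilityTable, rate: float) -> DiscountedOutcome:
    """Convenience wrapper returning discounted and undiscounted totals."""
    return DiscountedOutcome(
        cost=accrue_costs(traj, costs, rate),
        qalys=accrue_qalys(traj, utils, rate),
        cost_undiscounted=accrue_costs(traj, costs, 0.0),
        qalys_undiscounted=accrue_qalys(traj, utils, 0.0),
    )
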