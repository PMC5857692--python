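"""Incremental cost-effectiveness analysis, PSA and convergence checks.

The model runs twice over the same population — once per arm — under
common random numbers: each individual's simulation stream is seeded from
(master seed, stream tag, individual index) with no arm component, so the
arms differ only through parameters. With a null adherence effect and null
treatment effects the two arms produce bit-identical trajectories and the
increments are exactly zero; with real effects the variance of the
increments is sharply reduced.

Probabilistic sensitivity analysis draws one parameter set per iteration
from per-parameter distributions (lognormal for relative risks, beta for
probabilities, gamma for costs by default) and, when enabled, one
non-parametric bootstrap resample of the population (sampling individuals
with replacement at the original size), then reruns both arms and records
the incremental pair (ΔC, ΔE). The cost-effectiveness acceptability curve
is the fraction of iterations with positive net monetary benefit at each
willingness-to-pay value.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import ParameterSet, ScenarioConfig
from .economics import DiscountedOutcome, discounted_outcome
from .engine import Trajectory, simulate_individual
from .errors import ConfigurationError, ContractError
from .population import Individual

# RNG stream tags (ingredients of SeedSequence entropy tuples)
_SIM_STREAM = 101
_PSA_PARAM_STREAM = 202
_PSA_BOOT_STREAM = 303


def individual_rng(master_seed: int, index: int,
                   iteration: int | None = None) -> np.random.Generator:
    """Simulation stream for one individual; identical across arms."""
    entropy = (master_seed, _SIM_STREAM, index) if iteration is None \
        else (master_seed, _SIM_STREAM, iteration, index)
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))


@dataclass
class ArmResult:
    arm: str
    outcomes: list                      # list[DiscountedOutcome]
    trajectories: list                  # list[Trajectory]

    @property
    def mean_cost(self) -> float:
        return float(np.mean([o.cost for o in self.outcomes]))

    @property
    def mean_qalys(self) -> float:
        return float(np.mean([o.qalys for o in self.outcomes]))

    def n_cvd_events(self) -> int:
        return sum(t.n_cvd_events() for t in self.trajectories)

    def adherence_prevalence(self) -> float:
        """Fraction adherent in the first risk period."""
        flags = []
        for t in self.trajectories:
            flags.append(1.0 if (t.exposure and t.exposure[0].adherent)
                         else 0.0)
        return float(np.mean(flags)) if flags else 0.0


def run_arm(pop: Sequence[Individual], params: ParameterSet, arm: str,
            master_seed: int, iteration: int | None = None,
            keep_trajectories: bool = True) -> ArmResult:
    scenario = ScenarioConfig(arm=arm, master_seed=master_seed, n=len(pop))
    outcomes, trajs = [], []
    rate = params.discount_rate
    for i, ind in enumerate(pop):
        rng = individual_rng(master_seed, i, iteration)
        traj = simulate_individual(ind, scenario, params, rng)
        outcomes.append(discounted_outcome(traj, params.costs,
                                           params.utilities, rate))
        if keep_trajectories:
            trajs.append(traj)
    return ArmResult(arm=arm, outcomes=outcomes, trajectories=trajs)


def run_scenarios(pop: Sequence[Individual], params: ParameterSet,
                  master_seed: int,
                  iteration: int | None = None) -> dict[str, ArmResult]:
    """Both arms over the same population under common random numbers."""
    if len(pop) == 0:
        raise ContractError("empty population")
    return {arm: run_arm(pop, params, arm, master_seed, iteration)
            for arm in ("usual", "polypill")}


@dataclass
class CEAResult:
    mean_cost_usual: float
    mean_cost_polypill: float
    mean_qalys_usual: float
    mean_qalys_polypill: float
    delta_cost: float
    delta_qalys: float
    icer: float | None                   # None when undefined or dominated
    dominance: str | None                # "dominant" | "dominated" | None
    nmb: dict = field(default_factory=dict)   # wtp -> net monetary benefit
    psa_cloud: np.ndarray | None = None       # (n_iter, 2): ΔC, ΔE
    ceac: dict = field(default_factory=dict)  # wtp -> P(NMB > 0)


def icer_and_nmb(usual: ArmResult, polypill: ArmResult,
                 wtp_values: Sequence[float]) -> CEAResult:
    """Incremental analysis: ΔC, ΔE, ICER (or dominance label) and net
    monetary benefit NMB(λ) = λ·ΔE − ΔC at each willingness-to-pay."""
    dc = polypill.mean_cost - usual.mean_cost
    de = polypill.mean_qalys - usual.mean_qalys
    dominance = None
    icer = None
    if de == 0.0 and dc == 0.0:
        pass  # identical arms: no ratio, no dominance
    elif dc <= 0.0 and de >= 0.0:
        dominance = "dominant"           # cheaper and at least as effective
    elif dc >= 0.0 and de <= 0.0:
        dominance = "dominated"
    elif de != 0.0:
        icer = dc / de
    nmb = {float(w): float(w) * de - dc for w in wtp_values}
    return CEAResult(
        mean_cost_usual=usual.mean_cost,
        mean_cost_polypill=polypill.mean_cost,
        mean_qalys_usual=usual.mean_qalys,
        mean_qalys_polypill=polypill.mean_qalys,
        delta_cost=dc, delta_qalys=de, icer=icer, dominance=dominance,
        nmb=nmb)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis

@dataclass
class PSASpec:
    """How many iterations, which parameters vary and how.

    ``distributions`` maps dotted parameter paths into the resolved
    configuration (e.g. ``treatment_effects.rr_cvd_statin``,
    ``costs.acute.stroke``) to distribution specs — dicts with a ``kind``
    key: ``lognormal`` (sigma on the log scale, centred on the point
    value), ``beta`` (method-of-moments around the point value with
    ``sd``), ``gamma`` (point-value mean with coefficient of variation
    ``cv``) or ``fixed``.
    """

    n_iterations: int = 200
    distributions: dict = field(default_factory=dict)
    bootstrap: bool = True
    master_seed: int = 0

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        for path, spec in self.distributions.items():
            if spec.get("kind") not in ("lognormal", "beta", "gamma", "fixed"):
                raise ConfigurationError(
                    f"PSA distribution for {path!r} has unknown kind "
                    f"{spec.get('kind')!r}")


def default_psa_distributions() -> dict:
    """Standard health-economics families for the main scalar inputs."""
    logn = {"kind": "lognormal", "sigma": 0.10}
    return {
        "treatment_effects.rr_cvd_statin": dict(logn),
        "treatment_effects.rr_cvd_aht": dict(logn),
        "treatment_effects.rr_cvd_aspirin": dict(logn),
        "treatment_effects.rr_diabetes_tx": dict(logn),
        "treatment_effects.rr_gi_bleed_aspirin": dict(logn),
        "treatment_effects.rr_hf_aht": dict(logn),
        "treatment_effects.p_cough_acei": {"kind": "beta", "sd": 0.01},
        "adherence_rr.rr": {"kind": "lognormal", "sigma": 0.06},
        "case_fatality.stroke_lt75": {"kind": "beta", "sd": 0.02},
        "case_fatality.stroke_ge75": {"kind": "beta", "sd": 0.03},
        "costs.acute.stroke": {"kind": "gamma", "cv": 0.2},
        "costs.acute.mi": {"kind": "gamma", "cv": 0.2},
        "costs.annual_state.stroke": {"kind": "gamma", "cv": 0.2},
        "costs.monitoring_annual": {"kind": "gamma", "cv": 0.2},
    }


def _set_path(tree: dict, path: str, value) -> None:
    keys = path.split(".")
    node = tree
    for k in keys[:-1]:
        if k not in node:
            raise ConfigurationError(f"PSA path {path!r}: no node {k!r}")
        node = node[k]
    if keys[-1] not in node:
        raise ConfigurationError(f"PSA path {path!r}: no leaf {keys[-1]!r}")
    node[keys[-1]] = value


def _get_path(tree: dict, path: str):
    node = tree
    for k in path.split("."):
        node = node[k]
    return node


def _draw(point: float, spec: dict, rng: np.random.Generator) -> float:
    kind = spec["kind"]
    if kind == "fixed":
        return point
    if kind == "lognormal":
        return float(point * math.exp(rng.normal(0.0, spec["sigma"])))
    if kind == "beta":
        sd = spec["sd"]
        if point <= 0.0 or point >= 1.0 or sd <= 0.0:
            return point
        var = min(sd * sd, point * (1 - point) * 0.99)
        nu = point * (1 - point) / var - 1.0
        return float(rng.beta(point * nu, (1 - point) * nu))
    if kind == "gamma":
        cv = spec["cv"]
        if point <= 0.0 or cv <= 0.0:
            return point
        shape = 1.0 / (cv * cv)
        return float(rng.gamma(shape, point / shape))
    raise ConfigurationError(f"unknown distribution kind {kind!r}")


def sample_parameters(params: ParameterSet, distributions: dict,
                      rng: np.random.Generator) -> ParameterSet:
    """One PSA draw: each listed parameter sampled around its point value."""
    tree = params.to_dict()
    for path, spec in distributions.items():
        point = float(_get_path(tree, path))
        _set_path(tree, path, _draw(point, spec, rng))
    return ParameterSet.from_dict(tree)


@dataclass
class PSAResult:
    cloud: np.ndarray                     # (n_iter, 2): ΔC, ΔE
    ceac: dict                            # wtp -> acceptability
    base_case: CEAResult


def ceac_from_cloud(cloud: np.ndarray, wtp_values: Sequence[float]) -> dict:
    out = {}
    dc, de = cloud[:, 0], cloud[:, 1]
    for w in wtp_values:
        out[float(w)] = float(np.mean(w * de - dc > 0.0))
    return out


def bootstrap_indices(n: int, master_seed: int, iteration: int) -> np.ndarray:
    """Non-parametric bootstrap resample: n individuals drawn with
    replacement from an n-person population (resample size = original)."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(
        (master_seed, _PSA_BOOT_STREAM, iteration))))
    return rng.integers(0, n, size=n)


def run_psa(pop: Sequence[Individual], psa: PSASpec, params: ParameterSet,
            wtp_values: Sequence[float] = (20000.0, 30000.0)) -> PSAResult:
    """PSA with optional population bootstrap (resample size = len(pop))."""
    psa.validate()
    for path, spec in psa.distributions.items():
        if "kind" not in spec:
            raise ConfigurationError(
                f"no distribution kind for sampled parameter {path!r}")
    n = len(pop)
    cloud = np.empty((psa.n_iterations, 2))
    for k in range(psa.n_iterations):
        prng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(
            (psa.master_seed, _PSA_PARAM_STREAM, k))))
        params_k = sample_parameters(params, psa.distributions, prng)
        if psa.bootstrap:
            idx = bootstrap_indices(n, psa.master_seed, k)
            pop_k = [pop[i] for i in idx]
        else:
            pop_k = list(pop)
        # simulation streams are common across iterations (seeded by
        # position in the resample): iteration-to-iteration variation comes
        # only from the parameter draw and the bootstrap resample, the two
        # uncertainty layers of the analysis; degenerate distributions with
        # bootstrap off therefore reproduce the base case exactly
        arms = {arm: run_arm(pop_k, params_k, arm, psa.master_seed,
                             keep_trajectories=False)
                for arm in ("usual", "polypill")}
        cloud[k, 0] = arms["polypill"].mean_cost - arms["usual"].mean_cost
        cloud[k, 1] = arms["polypill"].mean_qalys - arms["usual"].mean_qalys
    base = run_scenarios(pop, params, psa.master_seed)
    return PSAResult(cloud=cloud,
                     ceac=ceac_from_cloud(cloud, wtp_values),
                     base_case=icer_and_nmb(base["usual"], base["polypill"],
                                            wtp_values))


# ---------------------------------------------------------------------------
# convergence

@dataclass
class ConvergenceReport:
    stable: bool
    rel_half_width: float
    recommended_n: float      # may be inf when tolerance is 0
    flagged: bool = False     # degenerate tolerance / zero mean


def convergence_check(values: Sequence[float], rel_tol: float = 0.01,
                      min_iterations: int = 10) -> ConvergenceReport:
    """Is the running mean stable to within ``rel_tol`` (95% CI half-width
    relative to |mean|)?  A zero tolerance is flagged, never looped on."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ContractError("need at least 2 iterations")
    mean = x.mean()
    sd = x.std(ddof=1)
    half = 1.959963984540054 * sd / math.sqrt(x.size)
    if sd == 0.0:
        return ConvergenceReport(stable=x.size >= min_iterations,
                                 rel_half_width=0.0,
                                 recommended_n=float(min_iterations))
    if rel_tol <= 0.0 or mean == 0.0:
        return ConvergenceReport(stable=False, rel_half_width=math.inf,
                                 recommended_n=math.inf, flagged=True)
    rel = half / abs(mean)
    needed = (1.959963984540054 * sd / (rel_tol * abs(mean))) ** 2
    return ConvergenceReport(
        stable=bool(rel <= rel_tol and x.size >= min_iterations),
        rel_half_width=float(rel),
        recommended_n=float(max(needed, min_iterations)))


# ---------------------------------------------------------------------------
# named sensitivity overlays

def sensitivity_overlay(params: ParameterSet, name: str,
                        value: float) -> ParameterSet:
    """One-dial sensitivity analyses: polypill price, per-protocol
    adjustment, discount rate."""
    tree = params.to_dict()
    if name == "polypill_price":
        tree["costs"]["polypill_annual"] = float(value)
    elif name == "itt_adjustment":
        tree["treatment_effects"]["itt_adjustment"] = float(value)
    elif name == "discount_rate":
        tree["discount_rate"] = float(value)
    else:
        raise ConfigurationError(
            f"unknown sensitivity {name!r}; expected polypill_price, "
            "itt_adjustment or discount_rate")
    return ParameterSet.from_dict(tree)
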