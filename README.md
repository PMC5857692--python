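# polypillsim

Individual-level discrete-event simulation (DES) of the long-term
cost-effectiveness of a cardiovascular **polypill** (a fixed-dose
combination of aspirin, a statin and two blood-pressure-lowering agents,
one an ACE inhibitor) versus **usual care** with the same drugs as
separate prescriptions, from an NHS/PSS perspective.

The package is for health-economic modellers and methods researchers: it
generates a synthetic high-CVD-risk adult cohort, drives each person
through a lifetime of events with risk-algorithm-based hazards, converts
the resulting trajectories into discounted costs and QALYs, and produces
incremental cost-effectiveness results with probabilistic sensitivity
analysis.

## The model in brief

* **Population.** Adults with established atherothrombotic CVD or a
  5-year CVD risk ≥ 15% (the classic fixed-dose-combination trial entry
  criteria). The cohort is synthetic: parametric marginals joined by a
  Gaussian copula (`polypillsim.population`).
* **Risks.** Proportional-hazards style engines in the QRISK2 family
  functional form: over a horizon *H*,
  `risk = 1 − S₀^exp(lp)`, `lp = Σᵢ wᵢ·xᵢ`,
  with a primary CVD engine (10-year horizon), a recurrent-event engine
  for people with established CVD, and an incident-diabetes engine.
  Horizon risks become constant hazards `λ = −ln(1−p)/H`, refreshed after
  every event or every 10 years.
* **Adherence.** The trial endpoint (statin, antiplatelet and ≥2
  antihypertensives each used on ≥4 of the preceding 7 days) is modelled
  as a logistic regression under usual care; the polypill multiplies each
  person's adherence probability by a relative risk (default 1.3,
  estimable from a two-arm trial dataset by log-binomial regression),
  capped at 1. Cessation is a constant-hazard process.
* **Events.** Competing exponential clocks for composite CVD (split into
  TIA / stroke / MI / angina by relative incidence), diabetes onset, GI
  bleeding, heart failure, cessation and other-cause death from a life
  table; acute case fatality for stroke (60 days) and MI (30 days) by age
  band; ACE-inhibitor cough as a one-shot probability at initiation.
  Simulation runs to death or age 100.
* **Economics.** Continuous-time discounting at 3.5%/year; acute event
  costs, lifelong post-event state costs, drug/monitoring flows, a
  stopping cost at cessation; EQ-5D-style age/sex baseline utilities with
  additive decrements floored at 0.
* **Analysis.** Both arms run under common random numbers; ΔC, ΔE, ICER
  (`ΔC/ΔE`), net monetary benefit `NMB(λ) = λ·ΔE − ΔC`, PSA with
  per-parameter distributions plus non-parametric bootstrap of the
  population, acceptability curves and convergence diagnostics.

All coefficient tables, the life table, costs and utilities ship as
*illustrative* defaults in the published functional forms and are
replaceable through configuration (CSV tables / YAML overlays).

## Worked example

```python
from polypillsim import analysis, config, population, risk

params = config.ParameterSet()          # packaged illustrative defaults
cohort = population.build_cohort(
    4000, population.PopulationSpec(seed=1),
    lambda ind: risk.five_year_risk(ind, params.primary_coeffs),
    threshold=params.inclusion_threshold)

arms = analysis.run_scenarios(cohort, params, master_seed=1)
r = analysis.icer_and_nmb(arms["usual"], arms["polypill"], (20000.0,))
print(f"ΔC = £{r.delta_cost:.0f}  ΔE = {r.delta_qalys:.3f} QALYs  "
      f"{'ICER £%.0f/QALY' % r.icer if r.icer else r.dominance}")
print(f"NMB(£20,000) = £{r.nmb[20000.0]:.0f}")
```

Output with these seeds and the packaged defaults:

```
ΔC = £-475  ΔE = 0.127 QALYs  dominant
NMB(£20,000) = £3006
```

Read: over a 4,000-person cohort the polypill arm costs £475 less per
person (better adherence avoids enough acute and chronic event costs to
more than offset the extra drug consumption) and gains 0.127 discounted
QALYs, so the polypill *dominates* usual care here; the net monetary
benefit at £20,000/QALY is about £3,000 per person. These numbers
describe the illustrative default inputs, not any published evaluation.

The same run is available from the shell:

```bash
polypillsim run --out results/base   # writes summary.json + manifest
polypillsim psa --iterations 200 --out results/psa
```

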