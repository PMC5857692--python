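# Methods

This note documents the model implemented by `polypillsim`: its structure
and assumptions, the defaults it ships with and why, the synthetic-data
generators, numerical conventions, and what the test suite does and does
not establish.

## Decision problem and model structure

The model compares two strategies for adults at high cardiovascular risk
who are indicated for full preventive therapy (a statin, an antiplatelet
and two blood-pressure-lowering agents, one an ACE inhibitor):

* **usual care** — the four drugs prescribed separately;
* **polypill** — the same pharmacology in one fixed-dose combination,
  whose only modelled clinical difference is *higher adherence*.

Both arms therefore carry the same indicated regimen; the arms differ in
the per-period probability that a person actually takes it, and (via a
price override) possibly in its cost. This is the cleanest reading of the
underlying trial design, and it makes the null scenario exact: with the
adherence relative risk and all treatment relative risks set to 1, the
two arms are the same stochastic process.

The model is an individual-level discrete-event simulation. A cohort
model with fixed cycles cannot carry each person's risk-factor profile
and event history without an explosion of states; a DES records events at
exact continuous times, updates the person's state, and accrues costs and
QALYs as it goes.

## Event simulation

At every *state point* (entry, any event, or a scheduled refresh) the
engine computes cause-specific yearly hazards and samples one exponential
clock per cause:

| cause | hazard source |
|---|---|
| composite CVD (TIA/stroke/MI/angina) | primary risk engine before the first CVD event; recurrent-event engine afterwards; × treatment RRs while adherent |
| diabetes onset | diabetes engine while non-diabetic; × treatment RR (statin/antihypertensive) while adherent |
| GI bleed | constant baseline (default 0.001/yr); × aspirin RR while adherent |
| heart failure | age-interpolated incidence table, once per lifetime; × antihypertensive RR while adherent |
| cessation | constant hazard while on treatment (default 0.05/yr) |
| other-cause death | life table, piecewise-exponential within years of age |

The earliest clock fires unless the deterministic risk refresh (every 10
years — the primary engine predicts a 10-year risk) or the age cap (100
years) comes first. Exponential clocks are memoryless, so discarding and
resampling all clocks at each state point is statistically equivalent to
carrying them forward; it also fixes the number of random draws per state
point, which is what makes common random numbers across arms exact.

Horizon risks become hazards by `λ = −ln(1−p)/H`, i.e. a constant hazard
between refresh points that reproduces the engine's cumulative risk at
the horizon exactly.

Event resolution: a composite CVD firing is split into TIA/stroke/MI/
angina by a relative-incidence vector; stroke and MI draw acute case
fatality by age band, and a fatal event ends the trajectory at the event
time plus the case-fatality window (60 days for stroke, 30 for MI).
Survivors re-enter the loop with the event appended to their history,
which switches them to the recurrent-event engine. Angina and TIA are
never acutely fatal (case fatality is specified only for stroke and MI).
Any clinical event is also an update point: risks refresh, adherence is
re-drawn, and the 10-year clock restarts.

ACE-inhibitor cough is a one-shot Bernoulli at treatment initiation (the
evidence base reports a placebo-adjusted probability, not a rate). The
draw is skipped entirely when the probability is zero so that draw
sequences stay aligned in null comparisons.

## Risk engines

All three engines share the QRISK2-family functional form
`risk = 1 − S₀^exp(lp)` with named covariate transforms, so published
coefficient sets are drop-in CSV replacements. The packaged defaults are
**illustrative**: they have the right signs, plausible magnitudes and the
published horizons (10 years for primary CVD and diabetes), but they are
not the published coefficient values. The recurrent-event engine's
horizon is not fixed by its sources; the default is 5 years and it is
configurable. The recurrent-event composite is split into the four
modelled types with the same relative-incidence vector as first events —
an assumption, flagged here, since the composite's published outcome mix
differs.

Trial inclusion historically used a 5-year risk threshold while the
modelling engine predicts 10-year risk. The default inclusion engine
converts under a constant hazard: `p₅ = 1 − (1−p₁₀)^(5/10)`; any other
engine can be plugged in.

## Adherence

Usual-care adherence is a logistic regression on individual
characteristics (defaults: older people more adherent, more deprived less
adherent). "Generalised linear mixed" in the motivating design is
implemented as a fixed-effects fit — the synthetic data carry no
clustering; a random-intercept extension would slot into
`fit_adherence_model`. The polypill multiplies each person's probability
by a relative risk on the risk scale (matching the log-binomial RR that
the estimation routine produces), capped at 1. Adherence status is
re-drawn at every update point, not continuously. Cessation is permanent:
treatment effects stop, drug and monitoring costs stop, and a one-off
stopping cost (default £80, e.g. two GP visits) is charged.

The default adherence RR is 1.3 with CI (1.15, 1.47) — the kind of
mid-teens relative improvement fixed-dose-combination trials report.

## Treatment effects

Class relative risks on CVD combine multiplicatively (independence across
classes, consistent with per-class meta-analytic sourcing): defaults
statin 0.75, antihypertensive 0.80, aspirin 0.90 (joint 0.54). Adverse
effects: diabetes RR 1.10 (statin/AHT), GI bleed RR 1.60 (aspirin), cough
probability 0.05 (ACE inhibitor), heart-failure RR 0.72 (AHT).
`itt_adjustment` exponentiates each log-RR, exposing the
intention-to-treat vs per-protocol sensitivity as one dial (1 = ITT as
supplied; values > 1 strengthen effects as a per-protocol proxy).

## Economics

Discounting is continuous-time at the NICE rate (3.5%/year): point costs
at exact event times scale by `(1+r)^(−t)`; yearly flows integrate to
`c·((1+r)^(−a) − (1+r)^(−b))/ln(1+r)`. A DES has no cycles, so this is
the natural analogue of annual discounting, and rate 0 reduces exactly to
undiscounted sums.

Costs: acute per-event costs; chronic state costs from the *first* event
of each type for life (repeat events re-trigger the acute cost only);
drug costs while on treatment **and adherent** (pills actually consumed);
monitoring while on treatment; the stopping cost once at cessation. The
polypill's yearly price defaults to the aggregate of its component drug
prices — so drug costs are identical across arms unless a sensitivity
price is set, and the polypill-price sweep moves only the polypill arm's
costs.

Utilities: age/sex baseline bands minus the sum of active decrements,
floored at 0 (additive decrements match decrement-style sourcing; the
floor prevents negative utility). GI bleed and cough carry transient
decrements (defaults 0.10 for 3 months and 0.02 for 1 year; the sources
give no durations, so these are configuration with no provenance claim).

All default costs and utilities are illustrative placeholders in the
right ranges for NHS reference-cost and EQ-5D-style inputs.

## Randomness and common random numbers

All randomness flows from one master seed through named substreams
(population; one simulation stream per individual, seeded from
(master seed, stream tag, individual index) with **no arm component**;
PSA parameter draws; bootstrap resampling). Identical streams across arms
make the null scenario exactly invariant and sharply reduce the variance
of increments. Within a PSA, simulation streams are also common across
iterations: iteration-to-iteration variation comes only from the
parameter draw and the bootstrap resample — the two uncertainty layers of
the analysis — so a degenerate PSA reproduces the base case exactly.

## Probabilistic sensitivity analysis

Each iteration draws one parameter set (default families: lognormal for
relative risks, beta for probabilities, gamma for costs, all centred on
the point values) and one bootstrap resample of the population
(individuals with replacement, resample size = original size), runs both
arms, and records (ΔC, ΔE). The acceptability curve is the fraction of
iterations with positive net monetary benefit at each willingness-to-pay.
`convergence_check` reports whether the 95% CI half-width of a running
mean is below a relative tolerance (default 1%) and recommends an
iteration count; a zero tolerance is flagged rather than looped on.

## Synthetic data

Two generators make the package self-contained:

* the **population generator** emulates the *structure* of a national
  health-survey sample (marginals, a Gaussian-copula correlation between
  age, blood pressure and BMI, prevalences of diabetes, prior CVD and
  medication use). It does not reproduce any real survey's joint
  distribution, survey weights, measurement error or missingness;
* the **trial generator** emulates the adherence endpoint of a two-arm
  fixed-dose-combination trial from a known logistic model and a known
  adherence RR.

Passing tests therefore establish that the machinery is correct — risks,
hazards, accrual, estimation and uncertainty propagate as specified —
not that the default numbers predict any real population's outcomes.
Substantive conclusions require published coefficient sets, national life
tables and costed inputs via the configuration layer.

The default life table is a synthetic Gompertz–Makeham table (ages
18–100, sex-specific level), shaped like a national table but not one;
a real table is a drop-in CSV (`age, sex, qx`).

## Numerical conventions and degenerate inputs

* Age-band edges are closed on the left (74.99 → <75 band, 75.0 → ≥75).
* An engine risk that reaches 1.0 in floating point is capped at
  1 − 10⁻¹² before hazard conversion; `risk_to_hazard` itself refuses
  p = 1 (infinite hazard).
* A life-table annual probability of 1 maps to a hazard of −ln(10⁻¹²),
  i.e. death within the year almost surely.
* Every stochastic clock consumes exactly one draw per state point even
  at zero hazard (time = ∞), keeping draw sequences aligned across
  compared scenarios.
* Entry at or above the age cap exits immediately with zero events; a
  fatal-event window that would cross the cap is truncated at the cap.
* Utility integration breaks the timeline at events, decrement expiries
  and age-band crossings; within segments utility is constant, so the
  discounted integral is exact (no quadrature error).
* Validation aggregates all configuration problems into one error.

## Problem sizes

Default analysis and verification sizes, chosen to keep Monte-Carlo error
well inside the assertion tolerances: base-case runs 4,000 individuals;
the life-table survival check 50,000; the competing-risk day-step
comparison 5,000 over 10 years; parameter-recovery checks 100 replicate
fits (n = 10,000 usual-care records for coefficients, 1,000 per arm for
the adherence RR); the directional check 50,000 individuals per arm; the
packaged PSA demonstration 30 iterations over 400 individuals. All are
configuration, not limits.

## Known limitations

* Default coefficients, costs and utilities are illustrative; results
  under defaults characterise the machinery, not the NHS.
* Treatment relative risks are assumed identical for primary and
  secondary prevention (per-engine overrides are available in the
  configuration).
* Cardiovascular hospitalisation as a distinct recurrent-event outcome is
  folded into the four-type split.
* No peripheral arterial disease events, renal impairment, falls or
  fractures, statin myopathy or liver dysfunction, or aspirin–cancer
  effects; no survey weighting; no value-of-information analysis.
* Partial adherence is not modelled: a person is adherent to the whole
  regimen or not, per the trial endpoint definition.
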