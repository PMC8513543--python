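# Methods

## Model structure

The model is a dynamic cohort Markov model of the Dutch kidney
replacement therapy (KRT) programme with a one-month cycle and a
120-cycle (10-year) horizon. "Dynamic" means the modelled population is
open: incident patients enter every cycle on top of the prevalent
cohort, and deaths leave through a single absorbing state.

Live states are the product of six treatment modalities (CHD, HHD,
CAPD, CCPD, DDKT, LDKT) and thirteen tenure slots. Slots 1–12 are
monthly tunnel states for the first year on a modality; slot "13+"
holds everyone beyond twelve months. Transition behaviour depends only
on the phase (first year vs subsequent years), not on the exact tunnel
slot, but the tunnels make the 12-month phase boundary exact under
monthly cycles: a cohort entering a modality reaches the subsequent
phase exactly at its thirteenth cycle. Switchers and incident patients
always enter the destination modality's tenure-1 slot. Optionally the
whole live grid is replicated over the six demographic groups (age
0–44 / 45–64 / 65+ × diabetic / non-diabetic), giving 79 or 469 states
including Death. Groups never interact, so the stratified model is six
independent cohorts sharing one death count.

The cohort is propagated in expectation: occupancies are nonnegative
reals, not integers. Conservation (initial + cumulative inflow = live +
cumulative deaths) holds each cycle to floating-point precision and is
asserted in the tests.

Prevalent patients at the start (16,917 on the reference date,
1 January 2018) are placed in the "13+" slot of their modality. Their
true tenure distribution is unknown; placing them all in the
subsequent-year phase is the conservative choice because first-year
transplant states carry much higher costs. This matters mainly for the
first simulated year.

## Economic accrual

Each cycle, start-of-cycle occupancy accrues 1/12 of the annual cost
and utility of its modality × phase. Costs (2018 euros) are discounted
at 4%/year, QALYs at 1.5%/year (Dutch guideline rates), with the smooth
monthly factor `(1 + r)^(−t/12)` rather than annual steps — annual
steps would create 11-month plateaus that interact badly with monthly
tunnel dynamics. There is no half-cycle correction; with monthly cycles
its effect is at most half a month of accrual at each end of the
horizon. Death accrues nothing from the cycle after death; terminal-care
costs are not modelled. Per-year outputs are per-year, not cumulative:
the year-2 row sums cycles 13–24 only. Intervention costs enter the cost
stream in the cycle the completer enters the model and are discounted at
the cost rate like every other cost.

Dialysis modalities carry one annual cost for all years; DDKT and LDKT
costs differ sharply by phase (first year includes the transplantation
itself: €106,210 / €78,297 vs €23,212 / €22,716 afterwards). This
phase asymmetry is what makes extra LDKTs cost-saving after year one.

## Parameter estimation

Transition probabilities are estimated from registry-style event
histories (one row per treatment episode). First-year annual counts use
the first twelve months of each modality spell; subsequent-year counts
pool spell-years 2–4, each spell-year contributing one Bernoulli trial
(event at the year it falls in, otherwise one "remain"). Spell-years
beyond the fourth contribute nothing. Censored partial years contribute
fractional exposure (months/12) to the remain count, so the Dirichlet
concentrations may be fractional; events under censoring are counted
fully. Empirical annual probabilities are the normalized counts, and the
same raw counts are the Dirichlet concentrations for the PSA, so the
Dirichlet mean equals the point estimate.

Annual → monthly conversion uses constant-hazard compounding on the
total leaving probability (`1 − (1 − q)^12 = A`) with cause-specific
shares preserved proportionally. This is the standard competing-risks-
consistent discretization; it exactly inverts the data-generating
process used by the synthetic registry, which is what makes parameter
recovery a sharp test. `A = 1` maps to the degenerate `q = 1`; `A > 1`
is rejected. Origins with no observed exposure fall back to a
pure-remain row and are reported as warnings.

Incidence is forecast per (group, modality): linear and log-linear
(exponential) least-squares fits on the annual incident counts, chosen
by residual sum of squares with ties going to linear. The nonlinear
family is fixed to the exponential because it is the natural monotone
alternative fittable by ordinary least squares on the log scale; series
with any zero year cannot enter it and use the linear fit. Series with
fewer than three nonzero years (configurable) use last observation
carried forward. Negative forecasts are clipped to zero; annual
forecasts divide by 12 into monthly inflow.

## Intervention scenarios

The intervention affects only LDKT rates. The effect size per incident
patient is `eligible (0.35) × completed (0.425) × effect`, with
`effect` 0.35 (optimistic), 0.18 (pessimistic) or 0 (base case). Two
design points the source material leaves open were resolved as follows:

- **Pre-emptive share (2/3).** That fraction of the effect reallocates
  incident inflow into LDKT, drawn proportionally from all non-LDKT
  starting modalities (nothing identifies which starts are displaced).
  Total inflow per cycle is conserved — patients are reallocated, never
  created.
- **Dialysis-to-LDKT share (1/3).** Spread evenly over a 24-month
  window (matching the 2-year follow-up in which the effect was
  measured) as an added monthly LDKT probability `delta` on the four
  dialysis first-year rows, applied by proportional renormalization:
  LDKT gains `delta`, every other destination (including death and
  remain) scales by `(1 − p_L − delta)/(1 − p_L)`. Because tenure
  tracking stops resolving at twelve months, the boost is carried by
  the first-year rows only; with the 24-month spreading denominator
  this realizes roughly half the nominal non-pre-emptive mass, which is
  the conservative reading. The window is configurable.

Everything — inflow reallocation, transition boost, intervention
costs — starts at cycle 7 ("after the first six cycles", when the first
trial effect was observed). Tying the cost start to the effect start
keeps increments internally consistent. Intervention cost is charged
per completer (incidence × 0.35 × 0.425 × €2,811) in the cycle of
entry, since the €2,811 was micro-costed per delivered intervention.
State utilities and costs are never modified by the scenario.

## Probabilistic sensitivity analysis

Per draw: utilities ~ beta, cost rows ~ gamma (one draw per printed
row — dialysis rows cover both phases jointly), each transition
origin/phase row ~ Dirichlet on the annual scale then converted to
monthly, intervention unit cost ~ gamma (mean €2,811, SE €281), and the
effect size scaled by a mean-one gamma multiplier with 20% relative SE
(gamma keeps the effect positive; the multiplier is shared across
scenarios within a draw). Beta and gamma shapes come from moment
matching, the only information available being printed means and SEs.
Blocks are drawn independently; no correlation structure is claimed by
the source material.

Every scenario is evaluated under the same parameter draw (common
random numbers), so per-draw increments isolate the intervention
effect; incremental uncertainty is then far smaller than the marginal
scenario uncertainty, as observed in the reference per-year tables.
Summaries report means and 2.5/97.5 percentile intervals. Two
probabilistic ICER conventions exist; the headline is the ratio of mean
increments, with the mean of per-draw ratios reported alongside,
because the reference per-year tables are not internally consistent
with either convention alone. Dominance is flagged when the mean
increments have ΔQALY > 0 and ΔCost < 0.

## Synthetic registry

The real national registry is not public, so all pipeline experiments
run on a synthetic stand-in with known ground truth. The generator
simulates individual histories month-by-month under (6 origin × 2
phase) monthly rows, with Poisson incident arrivals per calendar year
and 36 linear trends (about 2,000 incident patients/year; shares and
drifts chosen once to be order-of-magnitude realistic: dialysis
mortality ~12–15%/year, transplant mortality ~2%/year, rising LDKT and
slowly declining CHD starts). Demographics are assigned at entry from
the published 15/85 diabetic split crossed with a plausible age split
(15/40/45); the age split is a documented fixture, not published data.
Censoring happens only at the calibration-window end.

What the generator emulates: episode structure, first-year vs
subsequent-year rate differences, competing risks, group-specific
incidence trends, sparse cells that trigger LOCF. What it does not:
secular trends in transition rates, within-group heterogeneity,
waiting-list dynamics, measurement error and registration lag. Passing
recovery tests therefore demonstrates estimator correctness under the
model's own assumptions, not fidelity to Dutch epidemiology, and the
synthetic scenario results reproduce the qualitative dominance pattern,
not the published totals (which depend on non-public rates).

## Numerical choices and problem sizes

- Row-stochasticity is validated to 1e-9 on input and preserved to
  1e-12 by every transformation; conservation is checked to 1e-6
  relative each cycle.
- Recovery tests use a ~10,000-patient registry (5 years at ~2,000/year)
  and compare estimated annual probabilities to truth with binomial
  standard errors, and monthly probabilities with first-order
  (delta-method) standard errors; all 168 cells are required within
  3 SE at the fixed test seed.
- The cohort-vs-microsimulation cross-check uses a two-modality toy
  configuration (20,000 prevalent + 50/month incident, 24 cycles); the
  microsimulation samples whole patients and shares only the inputs
  with the engine, not code.
- PSA consistency checks run 5,000 draws; the engine evaluates one
  120-cycle scenario in a few milliseconds, so a full 3-scenario,
  5,000-draw PSA takes on the order of a minute.
- The analysis drivers use seed 2026 and 1,000 PSA draws as their
  default narrative size; the CLI defaults to 5,000 draws.

## Known limitations

- Patients do not age across age-band boundaries during the 10-year
  horizon; with group-constant transition rates this only affects the
  incidence mix, but it is a structural divergence risk for stratified
  analyses.
- Transitions are estimated pooled across demographic groups by
  default (the generator supports group-specific rates for sensitivity
  work).
- No deceased-donor waiting-list feedback: extra LDKTs do not shorten
  the modelled DDKT queue.
- No palliative/conservative-care pathway, no sex stratification, no
  acceptability curves or EVPI.
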