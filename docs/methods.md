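# Methods

## Model structure

The model is a deterministic cohort state-transition model over the seven
modified Rankin Scale (mRS) states, with mRS 6 (death) absorbing. Cycles
are 0.25 years; the cohort enters at 3 months post-ICH at its mean age
and is followed until the surviving mass falls below `survival_epsilon`
(10⁻⁹) or age reaches `max_age` (105 years).

Within the first year the transition matrices are derived from raw
patient counts: each observed row is normalised to proportions, and a row
with no observations becomes an identity row (the state retains itself)
so that the engine never renormalises silently. The 3→6-month matrix is
applied once; the pooled 6→12-month matrix is applied at both the 6→9 and
9→12-month steps, as the underlying counts do not separate the two
intervals. These matrices are the sole source of first-year mortality —
their death columns already contain the observed deaths — so background
mortality is deliberately *not* added during year 1 (it would be double
counted, and is an order of magnitude smaller than the observed risks).

Beyond one year the functional state is assumed stable: a patient either
stays put or dies. The quarterly death probability for alive state *s* at
age *a* is

    p(s, a) = 1 − exp(−HRₛ · h(⌊a⌋) / 4),   h(a) = −ln(1 − q(a)),

with q(a) the life table's annual death probability. Scaling is done on
the hazard scale rather than the probability scale so that any
non-negative hazard ratio yields a valid probability. Age advances 0.25
years per cycle but the life-table lookup floors to integer age; ages
beyond the table clamp to the terminal record (q = 1).

The hazard ratios are 1.0 for mRS 0–1 (an excess "hazard ratio of 0" is
read as *no additional risk*, i.e. a multiplier of one on background
mortality), 1.11 for mRS 2 and 2.38 for mRS 5. Values for mRS 3 and 4 are
not separately published; they default to the linear interpolation
(1.533, 1.957), which is monotone and reproducible, and can be overridden
in the config.

## Accrual

QALYs multiply each cycle's occupancy by the per-state annual utility and
the quarter-year cycle length, discounted at 1.5%/year; costs follow the
three-phase schedule — the one-off 0–3-month block charged undiscounted at
entry (together with the surgical cost in the MIS arm), the quarterly
3–12-month costs at the 6/9/12-month cycles, the long-term quarterly
costs thereafter — discounted at 4%/year. Time zero is model entry, and
membership at the start of a cycle determines that cycle's accrual. No
half-cycle correction is applied by default (the convention is exposed as
`EconSettings.half_cycle_correction`); whether the phase-1 block should
be discounted from ICH onset instead of entry is an open convention, and
entry-time zero is the documented choice here.

The 12-month cycle is charged at the phase-2 (3–12 month) rate; phase 3
starts at the first cycle beyond one year. The cost table's small
quarterly charge for the death state during months 3–12 (€5.30) is
applied to dead cohort mass like any other entry; because the trace stops
when no survivors remain, an all-dead cohort accrues exactly the phase-1
death cost (the extreme-value check).

Because the model is linear in its entry distribution, every analysis is
driven by per-entry-state discounted outcome vectors (one unit trace per
state, run without the epsilon stop so the decomposition is exact to
floating point). A dedicated test asserts that this decomposition
reproduces the two-trace comparison.

## Strategies

The MIS effect is a pure mass move on the entry distribution: state
*s* ≤ 3 gains ε·wₛ (weights 0.18/0.18/0.27/0.37), and the same total ε
leaves mRS 4–6 — by default proportionally to their occupancy, optionally
in equal thirds (the two rules coincide exactly when mRS 4–6 are equally
occupied, which is why the uniform worked example cannot distinguish
them; a test asserts this). Gains may land in states with zero occupancy;
losses can never exceed occupancy, and an infeasible ε raises an error
carrying the maximum feasible value. The operation conserves the input's
total mass, which lets it run unchanged on the literal 14.3%-per-state
illustrative vector (sum 1.001) used in the worked example.

Scenario shifts move an absolute fraction of the *whole cohort* (not of
the source state's occupants — both conventions circulate; this one is
consistent with how ε is defined in the main analysis) from one state to
the next-better one, with the surgical cost still charged to everyone.

## The four analyses

*Threshold effectiveness* is the smallest ε with iNMB ≥ 0 at fixed
surgical cost, found by bisection to 10⁻⁶ on ε over [0, max feasible ε]
(iNMB is monotone — in fact linear — in ε). *Threshold cost* is closed
form: C\* = λ·ΔE(ε) − ΔC_non-surgical(ε). The *two-way grid* marks the
preferred strategy per (ε, C) cell by the sign of the iNMB and carries
the break-even curve C\*(ε); a consistency test checks the curve against
the one-dimensional searches. *Scenario thresholds* bisect the shifted
fraction per source state over [0, occupancy]; a result can be infeasible
in two distinct ways that are reported separately — a non-positive
per-unit benefit ("never cost-effective", e.g. mRS 6→5, which buys
negative utility at the highest long-term cost) or a break-even fraction
exceeding the source state's occupancy.

In the probabilistic sensitivity analysis, transition rows and the entry
distribution are sampled from Dirichlet distributions with the observed
counts as concentrations (zero-count cells stay at zero); utilities for
mRS 0–4 from beta distributions matched by moments to the mean and 95%
CI (SE = CI width / 3.92), the negative-mean mRS 5 utility from a normal,
and costs from moment-matched gammas. These families are not dictated by
the evidence tables — they are the standard choices for probabilities,
bounded utilities and non-negative costs, and each block can be held
fixed. The surgical effectiveness and cost are treated as fixed design
parameters, and the hazard ratios and life table carry no published
uncertainty, so they are not sampled. Both arms share each sampled
parameter set (common random numbers). Point estimates of thresholds
under PSA are roots of the sample-mean iNMB; intervals are percentile
(2.5/97.5) over per-sample roots; a failed moment fit falls back to the
fixed mean with a logged warning. Per-sample effects saturate at that
sample's feasible maximum so sample-mean curves remain defined.

## Synthetic data

The bundled life table is Gompertz–Makeham, q(a) = 1 − exp(−(c + A·e^{Ba}))
with c = 5·10⁻⁴, A = 1.6·10⁻⁵, B = 0.102 over ages 18–110, calibrated
once so that remaining life expectancy at age 70 is 15.0 years — a
plausible elderly general population, deliberately *not* any national
dataset. Absolute results (lifetime QALYs, break-even costs) therefore
characterise the model under this synthetic mortality; reproducing
published country-specific figures requires substituting the national
life table CSV. Qualitative conclusions — break-even effectiveness near
one percentage point, decisions driven by effectiveness rather than cost,
the scenario ordering across source states — are insensitive to this
substitution, and those are what the test suite asserts. The generator
also produces Dirichlet-multinomial transition counts and synthetic
cohorts, which the tests use for parameter-recovery checks.

The individual-level microsimulation oracle replays the exact engine
rules (same matrices, same accrual schedule, population-level stop) for
*n* simulated patients and returns Monte-Carlo means with standard
errors; the cohort model is required to match it within 3 SEs on three
distinct parameter sets. The oracle shares no code path with the cohort
trace beyond the transition-matrix constructors.

What the synthetic generator does *not* emulate: correlated transition
counts across rows, age- or sex-stratified mortality, secular trends in
costs, or any treatment-dependent transition structure after entry.
Passing tests therefore demonstrate internal correctness and calibrated
behaviour under the stated assumptions, not agreement with any external
registry.

## Numerical conventions and sizes

Distribution validity is enforced at 10⁻⁹ (mass conservation), matrix
row sums at 10⁻¹²; bisection tolerance is 10⁻⁶ on the searched fraction.
The analysis drivers use 200–500 PSA samples and the microsimulation
tests 30,000–60,000 individuals, sizes at which Monte-Carlo error is
small relative to every asserted tolerance; the library default for PSA
remains 5,000 samples. All randomness flows through
`numpy.random.default_rng` seeds carried in the relevant settings
objects, so identical configuration and seed give byte-identical
outputs.

## Known limitations

Recurrent ICH and other cardiovascular events are outside the model; no
inter-mRS movement after one year; costs are 2019 euros with no
re-indexing; no societal/indirect costs, acceptability curves or
value-of-information analysis. The long-term cost estimate for mRS 2 is
markedly higher than for mRS 1 and 3 in the source table, which makes the
mRS 2→1 scenario threshold (and its feasibility within occupancy)
sensitive to the life table used.
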