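# Methods

## Model structure

The model is a time-homogeneous Markov cohort over four states in fixed
index order: controlled asthma (0), uncontrolled asthma (1), asthma
exacerbation (2), death from asthma exacerbation (3). The cohort is closed;
the base case starts with all mass in the uncontrolled state and runs 52
one-week cycles (a 364-day model year — day counts are reported on this
basis for internal consistency with the weekly cycle). Death is absorbing.
All transitions among the three alive states are permitted; death is
reached from the exacerbation state in the packaged configuration, but the
schema accepts any row-stochastic matrix, so a configuration may zero or
open any entry. Nothing varies by cycle within the one-year horizon, and no
discounting is applied (horizon ≤ 1 year).

## Strategy matrices from relative effects

Each comparator is the reference matrix plus two relative effects:

- *RR꜀* scales transitions **into** the controlled state, from the
  uncontrolled and exacerbation rows;
- *RRₑ* scales transitions **into** the exacerbation state, from the
  controlled and uncontrolled rows.

Scaled entries are clamped to [0, 1]; each row's residual probability is
reassigned to its stay/default state (controlled row → stays controlled;
uncontrolled and exacerbation rows → uncontrolled), keeping rows
stochastic. Death entries are never rescaled. If scaling leaves a negative
residual the parameter set is rejected as infeasible rather than silently
renormalised. Each effect can be declared a risk ratio (default,
multiplicative on the probability) or an odds ratio (applied on the odds
and mapped back); network-meta-analysis outputs are often reported on the
odds scale, so both are first-class. This destination-specific
multiplicative scheme with residual reassignment is the standard way to
push relative effects through a transition matrix while preserving row
sums; the exact algebra is a design choice of this package.

Re-referencing (the structural scenario that treats the reference matrix as
describing medium-dose ICS) divides every strategy's ratios by the new
reference strategy's ratios.

## Probability conversions and the half-cycle correction

Annual probabilities convert to cycle probabilities under a constant
hazard: p_cycle = 1 − (1 − p_annual)^(w/52) for a w-week cycle; the
conversion round-trips to 1e-12 and composing 52 independent weekly
Bernoulli survivals recovers the annual probability exactly. Accruals use
the trapezoidal half-cycle correction — the effective occupancy of cycle t
is the mean of the occupancies at its boundaries — applied uniformly to
costs, QALYs and day counts, so total accrual always lies between
start-counted and end-counted accrual.

## Costing

Resource-use profiles are annual for the controlled and uncontrolled states
(weekly cost = annual cost / 52) and per-episode for the exacerbation
state: each weekly cycle spent in that state incurs one full episode cost,
i.e. episodes last one cycle. Death costs zero. Maintenance inhalers are
costed at 12 devices dispensed per year (weekly cost = price × 12/52); the
package also implements the per-actuation formula (price per actuation ×
daily actuations × 7) because published descriptions of weekly inhaler
costing are ambiguous between the two — the annual-prescription mode is the
default since the 12-device assumption is stated explicitly, and the two
modes bracket the plausible readings. The reliever inhaler is a resource
item like any other. Two unit costs in the packaged configuration are
assumptions because the published cost table omits them despite non-zero
counts: pharmacist consultations (£14.00) and hospital outpatient
attendances (£186.00), both set at typical UK reference-cost magnitudes and
commented in the file. Money is a label (GBP 2019/20 as given); there is no
inflation machinery.

## Utilities

The controlled state carries the base utility (0.96); the uncontrolled and
exacerbation states deduct disutilities (0.10, 0.20). Deterministic
valuations enforce controlled ≥ uncontrolled ≥ exacerbation; probabilistic
draws are sampled independently per state and may legitimately cross, so
the sampler constructs valuations with the ordering check off.

## Incremental analysis

Strategies are ranked by effect; a strategy is dominated iff another costs
no more and delivers at least as much effect, strictly better on one axis.
Extended dominance iteratively removes any strategy whose sequential ICER
is at least that of the next, more effective, alternative; a point
collinear with its neighbours is economically redundant (a blend of its
neighbours matches it exactly) and is removed, so frontier ICERs are
strictly increasing. Exact (cost, effect) ties are merged for frontier
purposes and reported with a tie flag. ICERs are always computed from
unrounded model outputs: ratios of rounded table entries are not
reproducible and are never asserted. The effect measure is pluggable
(QALYs, controlled-asthma days, exacerbation-free days) with identical
frontier logic. Net monetary benefit (λE − C) drives probabilistic
summaries; the max-NMB rule and the largest-ICER-below-λ rule agree
everywhere, with ties broken identically (higher effect, then name).

## Deterministic sensitivity analyses

- **One-way utilities**: the uncontrolled and exacerbation utilities vary
  by ±0.05 one at a time (the base weight sits near the top of the scale,
  so it is varied only through its configured 95% interval, along with the
  disutility intervals). Each variant reports whether the
  cost-effectiveness rank ordering changed.
- **Price discount**: branded maintenance-inhaler prices scaled by
  (1 − f), f = 0.5 by default, emulating generic entry.
- **Exacerbation shift**: every alive-state transition into exacerbation is
  multiplied by 1.5 concurrently for all treatments, the added mass taken
  entirely from the same row's transition into the controlled state (the
  compensating state is named, not pro-rata); infeasible rows are rejected.
  The shift is applied to each strategy's final matrix.
- **Threshold price**: bisection on a strategy's device price in (0,
  current], re-screening dominance at every candidate (the frontier changes
  shape as the price falls), until the bracket is within £0.005; reports
  the price, the fractional reduction and the ICER at the found price. A
  threshold unreachable even at zero price raises a distinct error.

Scenario operations are pure: they deep-copy the configuration, and tests
assert the config digest is unchanged.

## Probabilistic sensitivity analysis

Uncertain parameters and their second-order distributions:

| parameter | distribution | fit |
|---|---|---|
| state utilities | gamma on (1 − u), SD fixed at 0.2 | method of moments; sampled utility = 1 − draw, truncated below at a configurable floor (default 0: utilities below zero are outside the valuation frame) |
| resource counts | lognormal (mean, SD per item) | σ² = ln(1 + (sd/m)²), μ = ln m − σ²/2; draws multiply fixed unit costs |
| transition probabilities | beta per uncertain matrix entry (mean, SD in the config) | method of moments; an interval-matching mode fits (α, β) to 2.5/97.5% bounds when only a credible interval is published |

All parameters are drawn independently (no correlation structure). The
relative effects are held fixed in the packaged configuration: their
posterior summaries are supplement-only, so uncertainty in the reference
matrix entries stands in for transition uncertainty. Rows rebalance on
their fixed stay entry after each draw; draws leaving a negative residual
are redrawn, redraws are counted, and a rate above 1% warns. Degenerate
specs (zero SD, zero mean) are point masses, so an all-point-mass run
reproduces the deterministic model bit for bit — a tested invariant, as is
bitwise reproducibility under a fixed seed. CEAC probabilities at each
willingness-to-pay value are the fraction of replicates in which a strategy
has maximal NMB, exact ties split equally, so curves sum to one at every
threshold. The default grid is £0–£50,000 in £1,000 steps.

## Synthetic configurations and known answers

`generate_config` draws complete configurations (row-stochastic matrix with
absorbing death, log-uniform relative effects on (0.2, 2] — symmetric on
the ratio scale, rejection-sampled for row feasibility — non-negative
resource means/SDs, positive unit costs, utilities from a base and two
deductions) deterministically from a seed. It emulates the *structure* of
the study parameters, not their joint distribution in real populations: no
correlation between resource use and transition risk, no seasonality, no
adherence effects — so passing tests demonstrate engine correctness, not
clinical validity of any particular configuration. Known-answer
configurations exercise the engine against closed forms derived
independently (geometric series): a static cohort (QALY = utility exactly),
geometric decay to death (half-cycle person-time = (1+q)/2 ×
(1−qⁿ)/(1−q)), and an analytic two-strategy ICER.

## Numerical choices

- Row sums: accepted within 1e-9; deviations below 1e-6 renormalised
  silently (forgiving rounding in hand-transcribed published matrices);
  larger deviations are errors naming the row. Occupancy conservation is
  asserted to 1e-9 everywhere.
- Trace vs explicit matrix-power oracle agrees to 1e-12 on short horizons.
- Threshold bisection tolerance: £0.005 on the device price.
- Beta interval fitting minimises squared quantile deviation over log
  concentration with the mean held fixed.
- Report rounding (pounds, 4 d.p. QALYs, 0.1 days) is applied only at
  output; internal computation is never rounded.

## Problem sizes

The analysis drivers run the full 10,000-replicate probabilistic analysis
(about half a minute on one core). The acceptance script uses 2,000
replicates for its structural PSA checks and a 2-replicate degenerate run
for the point-mass identity; the test suite uses 25–500 replicates per
test, 1,000 generated configurations for the conservation fuzz, and
200,000–400,000 draws for sampled-moment checks. These sizes are chosen so
the whole suite completes in seconds while keeping Monte-Carlo standard
errors well inside the asserted tolerances.

## Known limitations

- The packaged transition parameters are synthetic placeholders; totals,
  ICERs and CEAC probabilities computed from the example configuration are
  internally consistent but are not the published point estimates.
  Transcribing the published per-strategy matrices into the same schema is
  all that is needed to run the original analysis.
- Adverse events (e.g. adrenal or growth suppression under high-dose ICS)
  carry no cost or disutility.
- Parameter independence in the PSA ignores the joint posterior a network
  meta-analysis would imply; the sampler draws each parameter marginally.
- The model is cohort-level: no patient heterogeneity, no time-varying
  risk, no multi-year extrapolation.
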