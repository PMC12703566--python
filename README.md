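# asthmace

A cohort Markov cost-utility model of step-up treatment for children and
adolescents whose asthma remains uncontrolled on low-dose inhaled
corticosteroids (ICS), from the perspective of the UK NHS. The package
re-implements the EINSTEIN economic analysis as a tested, reusable library:
six comparator strategies (low/medium/high-dose ICS, ICS+LABA, ICS+LTRA and
LTRA monotherapy) are compared on costs, quality-adjusted life years
(QALYs), days of controlled asthma and exacerbation-free days over a
one-year horizon.

## The model

A closed cohort is distributed over four mutually exclusive health states —
*controlled asthma*, *uncontrolled asthma*, *asthma exacerbation* and
*death from asthma exacerbation* (absorbing) — and propagated in 52 weekly
cycles by a strategy-specific transition matrix **P**:

- the reference strategy (low-dose ICS) has matrix **P**₀; every comparator
  applies relative effects *RR꜀* (on transitions into the controlled state)
  and *RRₑ* (into the exacerbation state) multiplicatively, with the row
  residual reassigned to the row's stay/default state so rows remain
  stochastic. Odds ratios are supported via the odds scale.
- annual probabilities convert to weekly ones under a constant hazard,
  *p*₁ = 1 − (1 − *p*₅₂)^(1/52);
- costs, QALYs and day counts accrue with a half-cycle (trapezoidal)
  correction: the effective occupancy of cycle *t* is the mean of the
  occupancies at *t−1* and *t*. One cycle at full utility contributes
  1/52 QALY.

Strategies are ranked by effect, screened for dominance and extended
dominance, and the surviving frontier is summarised by incremental
cost-effectiveness ratios ICER = ΔC/ΔE against a £20,000/QALY threshold;
net monetary benefit (NMB = λ·E − C) underpins the probabilistic
acceptability curves. The probabilistic sensitivity analysis draws gamma
distributions on the disutility transform 1 − *u* (fixed SD 0.2), lognormal
resource-use counts, and beta transition probabilities, independently, and
re-runs the deterministic model per replicate.

The packaged example configuration encodes the published resource-use
counts, unit costs, inhaler prices and utilities (0.96 for controlled
asthma, with disutilities 0.10 and 0.20) verbatim; its transition
parameters are clearly flagged synthetic placeholders, since the published
per-strategy matrices appear only in an untranscribed supplementary
appendix. Any study can be run from a YAML/JSON configuration with the same
schema.

## Worked example

```python
from asthmace import load_example_config, run_base_case

result = run_base_case(load_example_config())
print(result.table_frame("qaly").round(4).to_string(index=False))
```

prints (costs in GBP per patient-year):

```
       strategy  total_cost  effect  incremental_cost  incremental_effect        icer               status
       ics_laba    464.2422  0.9427          182.6573              0.0021  85309.0226          on_frontier
medium_dose_ics    364.1698  0.9415               NaN                 NaN         NaN extendedly_dominated
  high_dose_ics    610.1409  0.9412               NaN                 NaN         NaN            dominated
       ics_ltra    399.7175  0.9406               NaN                 NaN         NaN            dominated
   low_dose_ics    281.5849  0.9405               NaN                 NaN         NaN          on_frontier
           ltra    319.8094  0.9333               NaN                 NaN         NaN            dominated
```

Low-dose ICS anchors the frontier; under the synthetic transition
placeholders ICS+LABA buys its extra 0.0021 QALYs at £85,309 each — far
above the £20,000/QALY threshold — and the other step-up options are
dominated (costlier and no more effective than an alternative). The
numbered drivers under `analysis/` run the full study: base case, one-way
and scenario sensitivity analyses, threshold inhaler prices, structural
variants, and a 10,000-replicate probabilistic analysis with
cost-effectiveness acceptability curves, writing their tables under
`results/`. The same stages are available from a shell via the `asthmace`
CLI (`run`, `icer`, `owsa`, `threshold`, `scenario`, `psa`, `ceac`,
`synth`, `validate`).

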