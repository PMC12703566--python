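#!/usr/bin/env python
"""Base-case cost-utility analysis of the six step-up strategies.

Runs the weekly-cycle cohort model on the packaged configuration (published
resource use, unit costs, inhaler prices and utilities; synthetic placeholder
transition parameters) and writes the per-strategy outcomes plus the three
incremental surfaces (QALYs, controlled-asthma days, exacerbation-free days)
under results/base/.
"""

from pathlib import Path

from asthmace import load_example_config, run_base_case
from asthmace.incremental import DominanceStatus
from asthmace.pipeline import run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "base"


def main() -> None:
    config = load_example_config()
    run_pipeline(config, "base", OUT)
    result = run_base_case(config)

    print("Base case (52 weekly cycles, cohort entering uncontrolled):\n")
    for s in result.strategies:
        o = s.outcomes
        print(
            f"  {s.label:24s} cost £{o.total_cost:7.2f}  QALY {o.total_qaly:.4f}  "
            f"controlled {o.controlled_days:5.1f} d  exacerbation {o.exacerbation_days:4.2f} d"
        )
    rows = result.tables["qaly"]
    frontier = [r for r in rows if r.status is DominanceStatus.ON_FRONTIER]
    dominated = [r.strategy for r in rows if r.status is not DominanceStatus.ON_FRONTIER]
    print("\nCost-per-QALY frontier (least to most effective):")
    for r in sorted(frontier, key=lambda r: r.effect):
        icer = "—" if r.icer is None else f"£{r.icer:,.0f}/QALY vs {r.comparator}"
        print(f"  {r.strategy:20s} {icer}")
    print(f"Dominated or extendedly dominated: {', '.join(dominated)}")
    print(f"\nTables written to {OUT}")


if __name__ == "__main__":
    main()
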