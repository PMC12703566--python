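#!/usr/bin/env python
"""Deterministic sensitivity analyses.

One-way variation of the uncontrolled/exacerbation utilities (±0.05 and
95% bounds), a 50% branded-inhaler price discount, a +50% exacerbation-risk
scenario, and threshold analyses of the inhaler prices at which ICS+LABA
and medium-dose ICS would meet £20,000/QALY. Results under
results/sensitivity/.
"""

from pathlib import Path

from asthmace import load_example_config, run_base_case, threshold_price
from asthmace.errors import ThresholdNotFoundError
from asthmace.incremental import DominanceStatus
from asthmace.pipeline import run_pipeline
from asthmace.sensitivity import exacerbation_shift_scenario, one_way_utility, price_discount_scenario

OUT = Path(__file__).resolve().parents[1] / "results" / "sensitivity"


def min_frontier_icer(result):
    icers = [
        r.icer
        for r in result.tables["qaly"]
        if r.status is DominanceStatus.ON_FRONTIER and r.icer is not None
    ]
    return min(icers) if icers else float("nan")


def main() -> None:
    config = load_example_config()
    run_pipeline(config, "owsa", OUT / "owsa")

    changed = [v.name for v in one_way_utility(config) if v.rank_order_changed]
    print(
        "One-way utility variation (±0.05): rank ordering "
        + ("changed for: " + ", ".join(changed) if changed else "unchanged in all variants")
    )

    base_icer = min_frontier_icer(run_base_case(config))
    discount = min_frontier_icer(price_discount_scenario(config))
    shift = min_frontier_icer(exacerbation_shift_scenario(config))
    print(f"Cheapest frontier step ICER — base £{base_icer:,.0f}/QALY, "
          f"50% branded discount £{discount:,.0f}/QALY, "
          f"+50% exacerbation risk £{shift:,.0f}/QALY")

    for strategy in ("ics_laba", "medium_dose_ics"):
        try:
            res = threshold_price(config, strategy)
        except ThresholdNotFoundError as exc:
            print(f"  {strategy}: {exc}")
            continue
        run_pipeline(config, "threshold", OUT / f"threshold_{strategy}", strategy=strategy)
        print(
            f"  {strategy}: device price £{res.current_price:.2f} → £{res.threshold_price:.2f} "
            f"({res.fraction_reduction:.1%} reduction) to reach £{config.wtp_threshold:,.0f}/QALY"
        )
    print(f"\nTables written to {OUT}")


if __name__ == "__main__":
    main()
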