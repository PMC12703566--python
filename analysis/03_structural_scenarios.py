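#!/usr/bin/env python
"""Structural uncertainty analyses.

Re-runs the incremental analysis under (i) random-effects relative effects,
(ii) the reference matrix assigned to medium-dose ICS, (iii) both, and
(iv) dose-stratified ICS+LABA strategies with individually priced inhalers.
Tables under results/structural/.
"""

from pathlib import Path

from asthmace import load_example_config
from asthmace.incremental import DominanceStatus, table_to_frame
from asthmace.pipeline import run_pipeline
from asthmace.sensitivity import STRUCTURAL_VARIANTS, structural_scenarios

OUT = Path(__file__).resolve().parents[1] / "results" / "structural"


def main() -> None:
    config = load_example_config()
    run_pipeline(config, "scenario", OUT)
    for variant in STRUCTURAL_VARIANTS:
        result = structural_scenarios(config, variant)
        rows = result.tables["qaly"]
        frontier = [r for r in rows if r.status is DominanceStatus.ON_FRONTIER]
        best = max(rows, key=lambda r: r.effect)
        print(f"{variant}:")
        print(f"  most effective: {best.strategy} ({best.effect:.4f} QALYs, £{best.cost:,.0f})")
        for r in sorted(frontier, key=lambda r: r.effect):
            if r.icer is not None:
                print(f"  frontier ICER {r.strategy} vs {r.comparator}: £{r.icer:,.0f}/QALY")
        if variant == "dose_stratified_laba":
            frame = table_to_frame(rows).set_index("strategy")
            med = frame.loc["medium_dose_ics_laba"]
            base_med = frame.loc["medium_dose_ics"]
            print(
                "  medium-dose ICS+LABA vs medium-dose ICS: "
                f"+£{med.total_cost - base_med.total_cost:,.0f}, "
                f"+{med.effect - base_med.effect:.4f} QALYs"
            )
    print(f"\nTables written to {OUT}")


if __name__ == "__main__":
    main()
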