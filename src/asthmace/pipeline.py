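"""Result serialisation and the analysis pipeline.

``run_pipeline`` executes one analysis stage on a validated configuration
and writes delimited result tables plus a JSON run manifest (seed, config
digest, package version) so every output file is traceable to its inputs.
CSV outputs start with a provenance comment line.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import ModelConfig, config_digest
from .errors import AsthmaceError
from .incremental import table_to_frame
from .model import EFFECT_MEASURES, run_base_case
from .psa import ceac, run_psa
from .sensitivity import (
    STRUCTURAL_VARIANTS,
    exacerbation_shift_scenario,
    one_way_utility,
    price_discount_scenario,
    structural_scenarios,
    threshold_price,
)

__all__ = ["ANALYSES", "run_pipeline"]

logger = logging.getLogger(__name__)

ANALYSES = ("base", "owsa", "threshold", "scenario", "psa", "ceac")


def _write_csv(frame: pd.DataFrame, path: Path, digest: str, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={digest} seed={seed} asthmace={__version__}\n")
        frame.to_csv(fh, index=False)


def _frontier_icer_summary(result, scenario: str) -> list[dict]:
    rows = []
    for row in result.tables["qaly"]:
        if row.icer is not None:
            rows.append(
                {
                    "scenario": scenario,
                    "strategy": row.strategy,
                    "comparator": row.comparator,
                    "icer": row.icer,
                }
            )
    return rows


def run_pipeline(
    config: ModelConfig,
    analysis: str,
    out_dir: str | Path,
    seed: int | None = None,
    replicates: int | None = None,
    wtp: float | None = None,
    strategy: str | None = None,
) -> Path:
    """Run one analysis stage and write its result bundle under ``out_dir``.

    Returns the output directory. Stage failures are re-raised with the
    stage name prefixed.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis '{analysis}'; expected one of {ANALYSES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    digest = config_digest(config)
    logger.info("running analysis '%s' (seed %d, config %s)", analysis, seed, digest[:12])

    try:
        if analysis == "base":
            result = run_base_case(config)
            for measure in EFFECT_MEASURES:
                _write_csv(
                    table_to_frame(result.tables[measure]),
                    out_dir / f"cea_{measure}.csv",
                    digest,
                    seed,
                )
            outcome_rows = [
                {
                    "strategy": r.name,
                    "label": r.label,
                    "total_cost": r.outcomes.total_cost,
                    "total_qaly": r.outcomes.total_qaly,
                    "controlled_days": r.outcomes.controlled_days,
                    "uncontrolled_days": r.outcomes.uncontrolled_days,
                    "exacerbation_days": r.outcomes.exacerbation_days,
                    "exacerbation_free_days": r.outcomes.exacerbation_free_days,
                }
                for r in result.strategies
            ]
            _write_csv(pd.DataFrame(outcome_rows), out_dir / "outcomes.csv", digest, seed)

        elif analysis == "owsa":
            variants = one_way_utility(config)
            summary = []
            for v in variants:
                _write_csv(
                    table_to_frame(v.result.tables["qaly"]),
                    out_dir / f"owsa_{v.name}.csv",
                    digest,
                    seed,
                )
                summary.append(
                    {
                        "variant": v.name,
                        "u_controlled": v.utilities[0],
                        "u_uncontrolled": v.utilities[1],
                        "u_exacerbation": v.utilities[2],
                        "rank_order_changed": v.rank_order_changed,
                    }
                )
            _write_csv(pd.DataFrame(summary), out_dir / "owsa_summary.csv", digest, seed)

        elif analysis == "threshold":
            if strategy is None:
                raise ValueError("threshold analysis requires a strategy name")
            res = threshold_price(config, strategy, wtp)
            payload = {
                "strategy": res.strategy,
                "wtp": wtp if wtp is not None else config.wtp_threshold,
                "current_price": res.current_price,
                "threshold_price": res.threshold_price,
                "fraction_reduction": res.fraction_reduction,
                "icer_at_threshold": res.icer_at_threshold,
                "config": digest,
                "seed": seed,
            }
            (out_dir / "threshold.json").write_text(json.dumps(payload, indent=2) + "\n")

        elif analysis == "scenario":
            summary_rows = _frontier_icer_summary(run_base_case(config), "base")
            discount = price_discount_scenario(config)
            _write_csv(
                table_to_frame(discount.tables["qaly"]),
                out_dir / "price_discount.csv",
                digest,
                seed,
            )
            summary_rows += _frontier_icer_summary(discount, "price_discount")
            shift = exacerbation_shift_scenario(config)
            _write_csv(
                table_to_frame(shift.tables["qaly"]),
                out_dir / "exacerbation_shift.csv",
                digest,
                seed,
            )
            summary_rows += _frontier_icer_summary(shift, "exacerbation_shift")
            for variant in STRUCTURAL_VARIANTS:
                try:
                    res = structural_scenarios(config, variant)
                except AsthmaceError as exc:
                    logger.info("skipping structural variant %s: %s", variant, exc)
                    continue
                _write_csv(
                    table_to_frame(res.tables["qaly"]),
                    out_dir / f"structural_{variant}.csv",
                    digest,
                    seed,
                )
                summary_rows += _frontier_icer_summary(res, variant)
            _write_csv(
                pd.DataFrame(summary_rows), out_dir / "scenario_summary.csv", digest, seed
            )

        elif analysis in ("psa", "ceac"):
            result = run_psa(config, n=replicates, seed=seed)
            _write_csv(result.samples, out_dir / "psa_samples.csv", digest, seed)
            _write_csv(result.summary, out_dir / "psa_summary.csv", digest, seed)
            if analysis == "ceac":
                curves = ceac(result, config.wtp_grid)
                _write_csv(curves, out_dir / "ceac.csv", digest, seed)
    except Exception as exc:
        raise type(exc)(f"[stage {analysis}] {exc}") from exc

    manifest = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "analysis": analysis,
        "seed": seed,
        "config_digest": digest,
        "config_name": config.name,
        "asthmace_version": __version__,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out_dir
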