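"""Deterministic model runs: config -> traces -> outcomes -> CEA tables.

This is the assembly layer used by the base case, every sensitivity
scenario and each probabilistic replicate: build a per-strategy transition
matrix from the reference matrix and relative effects, run the weekly
cohort trace, value it, and rank the strategies incrementally on a chosen
effect measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ALIVE_STATE_NAMES, ModelConfig, StrategyConfig
from .incremental import CEATableRow, build_cea_table, table_to_frame
from .markov import (
    CohortTrace,
    TransitionMatrix,
    apply_relative_effects,
    run_trace,
)
from .valuation import (
    Outcomes,
    ResourceItem,
    StateValuation,
    accrue,
    utilities_from_disutilities,
    weekly_inhaler_cost,
    weekly_state_cost,
)

__all__ = [
    "EFFECT_MEASURES",
    "StrategyResult",
    "BaseCaseResult",
    "build_strategy_matrix",
    "build_state_valuation",
    "run_strategy",
    "run_base_case",
]

#: Effect measures supported by the incremental analysis.
EFFECT_MEASURES = ("qaly", "controlled_days", "exacerbation_free_days")


@dataclass(frozen=True)
class StrategyResult:
    name: str
    label: str
    outcomes: Outcomes
    trace: CohortTrace


@dataclass(frozen=True)
class BaseCaseResult:
    """Per-strategy outcomes plus incremental tables per effect measure."""

    strategies: list[StrategyResult]
    tables: dict[str, list[CEATableRow]]

    def outcomes(self, name: str) -> Outcomes:
        for s in self.strategies:
            if s.name == name:
                return s.outcomes
        raise KeyError(f"unknown strategy '{name}'")

    def table_frame(self, measure: str = "qaly") -> pd.DataFrame:
        return table_to_frame(self.tables[measure])

    def entries(self, measure: str = "qaly") -> list[tuple[str, float, float]]:
        return [
            (s.name, s.outcomes.total_cost, s.outcomes.effect(measure))
            for s in self.strategies
        ]


def build_strategy_matrix(
    config: ModelConfig,
    strategy: StrategyConfig,
    reference_matrix: TransitionMatrix | None = None,
    random_effects: bool = False,
    rr_rescale: tuple[float, float] = (1.0, 1.0),
) -> TransitionMatrix:
    """Strategy transition matrix from the reference matrix plus effects."""
    if reference_matrix is None:
        reference_matrix = config.transition_matrix.matrix(config.cycle_length_weeks)
    spec = strategy.spec(random_effects=random_effects, rr_rescale=rr_rescale)
    return apply_relative_effects(reference_matrix, spec)


def weekly_drug_cost(config: ModelConfig, strategy: StrategyConfig) -> float:
    """Weekly maintenance-inhaler cost in the annual-prescription mode."""
    return weekly_inhaler_cost(
        strategy.device_price,
        mode="annual_devices",
        devices_per_year=config.drug_devices_per_year,
    )


def _resolve_items(
    items, strategy: StrategyConfig, count_overrides: dict[str, float] | None = None
) -> list[ResourceItem]:
    resolved = []
    for item in items:
        unit_cost = (
            strategy.device_price if item.cost_source == "strategy_device" else item.unit_cost
        )
        mean = item.mean
        if count_overrides is not None and item.name in count_overrides:
            mean = count_overrides[item.name]
        resolved.append(ResourceItem(item.name, mean, unit_cost, item.sd))
    return resolved


def build_state_valuation(
    config: ModelConfig,
    strategy: StrategyConfig,
    utilities: tuple[float, float, float] | None = None,
    count_overrides: dict[str, dict[str, float]] | None = None,
    check_ordering: bool = True,
) -> StateValuation:
    """Per-state weekly costs and utilities for one strategy.

    The controlled and uncontrolled profiles are annual and divided over 52
    cycles; the exacerbation profile is charged per episode, one episode per
    cycle spent in the state. Maintenance-inhaler items priced from the
    strategy's device price; ``count_overrides`` (state -> item -> count)
    lets the probabilistic sampler replace drawn resource counts.
    """
    if utilities is None:
        u = config.utilities
        utilities = utilities_from_disutilities(
            u.base, u.disutility_uncontrolled, u.disutility_exacerbation
        )
    costs = {}
    for state in ALIVE_STATE_NAMES:
        overrides = None if count_overrides is None else count_overrides.get(state)
        items = _resolve_items(config.resource_use[state], strategy, overrides)
        costs[state] = weekly_state_cost(items, per_episode=(state == "exacerbation"))
    return StateValuation.build(
        costs["controlled"],
        costs["uncontrolled"],
        costs["exacerbation"],
        utilities,
        check_ordering=check_ordering,
    )


def run_strategy(
    config: ModelConfig,
    strategy: StrategyConfig,
    reference_matrix: TransitionMatrix | None = None,
    matrix_transform=None,
    utilities: tuple[float, float, float] | None = None,
    random_effects: bool = False,
    rr_rescale: tuple[float, float] = (1.0, 1.0),
) -> StrategyResult:
    """Run one strategy end to end and accrue its outcomes.

    ``matrix_transform`` (matrix -> matrix) is applied to the strategy's
    final transition matrix; scenario analyses use it to perturb transition
    probabilities concurrently for all treatments.
    """
    matrix = build_strategy_matrix(
        config, strategy, reference_matrix, random_effects, rr_rescale
    )
    if matrix_transform is not None:
        matrix = matrix_transform(matrix)
    trace = run_trace(matrix, config.initial_occupancy(), config.n_cycles)
    valuation = build_state_valuation(config, strategy, utilities)
    return StrategyResult(strategy.name, strategy.label, accrue(trace, valuation), trace)


def run_base_case(
    config: ModelConfig,
    matrix_transform=None,
    utilities: tuple[float, float, float] | None = None,
    random_effects: bool = False,
    reference_strategy: str | None = None,
    strategies: list[StrategyConfig] | None = None,
) -> BaseCaseResult:
    """Run every strategy and build incremental tables per effect measure.

    ``reference_strategy`` re-references the relative effects: the reference
    matrix is taken to describe that strategy and every ratio is divided by
    its ratios (structural scenario ii/iii).
    """
    if strategies is None:
        strategies = config.strategies
    rr_rescale = (1.0, 1.0)
    if reference_strategy is not None and reference_strategy != config.reference_strategy:
        ref = config.strategy(reference_strategy)
        if random_effects:
            if (
                ref.rr_control_random_effects is None
                or ref.rr_exacerbation_random_effects is None
            ):
                raise KeyError(
                    f"strategy '{reference_strategy}' has no random-effects ratios"
                )
            rr_rescale = (ref.rr_control_random_effects, ref.rr_exacerbation_random_effects)
        else:
            rr_rescale = (ref.rr_control, ref.rr_exacerbation)
    reference_matrix = config.transition_matrix.matrix(config.cycle_length_weeks)
    results = [
        run_strategy(
            config,
            s,
            reference_matrix=reference_matrix,
            matrix_transform=matrix_transform,
            utilities=utilities,
            random_effects=random_effects,
            rr_rescale=rr_rescale,
        )
        for s in strategies
    ]
    tables = {
        measure: build_cea_table(
            [(r.name, r.outcomes.total_cost, r.outcomes.effect(measure)) for r in results]
        )
        for measure in EFFECT_MEASURES
    }
    return BaseCaseResult(results, tables)
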